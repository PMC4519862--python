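"""End-to-end orchestration: one config in, a report bundle out.

A :class:`RunConfig` (usually parsed from YAML) names either input files
(per-locus FASTA + popmap + coordinates) or a synthetic-study spec, the
analyses to run, and per-analysis options.  ``run`` executes the stages in
order — diversity stats, AMOVA + isolation by distance, parsimony
networks, ABC scenario choice with confidence evaluation — writing fixed-
column-order TSV artifacts (6 significant digits) plus GraphML networks
into the output directory, and echoing the config verbatim next to them.

A single top-level seed deterministically derives independent per-stage
seeds, so re-running the same config gives byte-identical outputs while
stages stay statistically independent.  A failing stage stops the stages
after it; artifacts already written are retained.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import diversity, network, structure
from .coalsim import LocusDesign
from .seq_io import Alignment, InputError, PopulationMap, read_fasta, read_tables
from .synthetic_data import (
    StudyDesign,
    generate_study,
    groups_for_scenario,
    scenario_library,
)

log = logging.getLogger("invabc.pipeline")

FLOAT_FORMAT = "%.6g"
STOCHASTIC_STAGES = {"stats", "structure", "abc", "synth"}
ALL_STAGES = ("synth", "stats", "structure", "network", "abc")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int | None = None
    analyses: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs: either explicit files ...
    loci: list[dict] = field(default_factory=list)   # name/inheritance/fasta
    popmap: str | None = None
    coords: str | None = None
    # ... or a synthetic-study spec
    synth: dict = field(default_factory=dict)        # scenario, full_length
    # per-analysis options
    n_perm: int = 10_000
    fs_null_sims: int = 1000
    abc_options: dict = field(default_factory=dict)  # scenarios, n_sims, ...
    raw_text: str = ""

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "out_dir" not in doc:
            raise InputError("config must be a mapping with an out_dir")
        cfg = cls(
            out_dir=Path(doc["out_dir"]),
            seed=doc.get("seed"),
            analyses=list(doc.get("analyses", ALL_STAGES)),
            loci=list(doc.get("loci", [])),
            popmap=doc.get("popmap"),
            coords=doc.get("coords"),
            synth=dict(doc.get("synth", {})),
            n_perm=int(doc.get("n_perm", 10_000)),
            fs_null_sims=int(doc.get("fs_null_sims", 1000)),
            abc_options=dict(doc.get("abc", {})),
            raw_text=text,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def validate(self) -> None:
        unknown = set(self.analyses) - set(ALL_STAGES)
        if unknown:
            raise InputError(f"unknown analyses: {sorted(unknown)}")
        if self.seed is None and (set(self.analyses) & STOCHASTIC_STAGES):
            raise InputError(
                "a seed is mandatory when stochastic stages "
                f"({sorted(set(self.analyses) & STOCHASTIC_STAGES)}) are requested"
            )
        if "synth" not in self.analyses and not self.loci:
            raise InputError("either a synth spec or input loci are required")


def _stage_seed(seed: int, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; return the artifact paths by name."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if config.raw_text:
        (out / "run_config.yaml").write_text(config.raw_text)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    def stage_log(stage: str, seed: int | None) -> None:
        log.info("stage=%s wall=%.1fs seed=%s", stage, time.perf_counter() - t0, seed)

    try:
        alignments: dict[str, Alignment] = {}
        popmap: PopulationMap | None = None
        coords = None
        truth_scenario = None

        if "synth" in config.analyses:
            seed = _stage_seed(config.seed, "synth")
            stage_log("synth", seed)
            design = StudyDesign.default(
                full_length=bool(config.synth.get("full_length", False))
            )
            study = generate_study(
                design,
                config.synth.get("scenario", "full_study"),
                seed=seed,
                out_dir=out / "synthetic_data",
            )
            alignments, popmap, coords = study.alignments, study.popmap, study.coords
            truth_scenario = study.truth["scenario"]
            artifacts.update(study.paths)
        else:
            for spec in config.loci:
                aln = read_fasta(spec["fasta"], spec["name"], spec["inheritance"])
                alignments[spec["name"]] = aln
            popmap, coords = read_tables(config.popmap, config.coords)

        if "stats" in config.analyses:
            seed = _stage_seed(config.seed, "stats")
            stage_log("stats", seed)
            for name, aln in alignments.items():
                rep = diversity.population_report(
                    aln, popmap, n_null_sims=config.fs_null_sims, seed=seed
                )
                p = out / f"diversity_{name}.tsv"
                _write(rep, p)
                artifacts[f"diversity_{name}"] = p

        if "structure" in config.analyses:
            seed = _stage_seed(config.seed, "structure")
            stage_log("structure", seed)
            mantel_rows = []
            for name, aln in alignments.items():
                res = structure.amova_two_level(
                    aln, popmap, n_perm=config.n_perm, seed=seed
                )
                p = out / f"amova_{name}.tsv"
                _write(res.to_frame(), p)
                artifacts[f"amova_{name}"] = p
                ibd = structure.isolation_by_distance(
                    aln, popmap, coords, n_perm=config.n_perm, seed=seed
                )
                mantel_rows.append(
                    {"locus": name, "r": ibd.r, "p": ibd.p, "n_perm": ibd.n_perm}
                )
            p = out / "mantel.tsv"
            _write(pd.DataFrame(mantel_rows), p)
            artifacts["mantel"] = p

        if "network" in config.analyses:
            stage_log("network", None)
            from .seq_io import collapse_haplotypes

            for name, aln in alignments.items():
                haps = collapse_haplotypes(aln, popmap)
                limit = network.connection_limit(
                    int(aln.complete_sites().sum()), 0.95
                )
                net = network.build_networks(haps, limit)
                gp = out / f"network_{name}.graphml"
                network.write_graphml(net, haps, gp, regions=popmap.regions)
                artifacts[f"network_{name}"] = gp
                sp = out / f"network_summary_{name}.tsv"
                _write(network.network_summary(net), sp)
                artifacts[f"network_summary_{name}"] = sp

        if "abc" in config.analyses:
            seed = _stage_seed(config.seed, "abc")
            stage_log("abc", seed)
            opts = config.abc_options
            lib = scenario_library()
            names = opts.get(
                "scenarios", ["cluster1_scenario5", "cluster1_usa_origin"]
            )
            models = [lib[n] for n in names]
            design = StudyDesign.default()
            groups = groups_for_scenario(design, models[0])
            loci = [
                LocusDesign(
                    name=ld.name, inheritance=ld.inheritance,
                    length=alignments[ld.name].length
                    if ld.name in alignments else ld.length,
                    sample_sizes=ld.sample_sizes,
                )
                for ld in design.locus_designs(groups)
            ]
            ref = abc_mod.build_reference_table(
                models, int(opts.get("n_sims", 2000)), loci, seed
            )
            grouped = PopulationMap(
                {s: groups.get(p, p) for s, p in popmap.assignments.items()
                 if p in groups}
            )
            sub = {
                name: aln.subset(
                    [s for s in aln.sample_ids
                     if popmap.population_of(s) in groups]
                )
                for name, aln in alignments.items()
            }
            observed = abc_mod.summarize_alignments(sub, grouped, loci)
            choice = abc_mod.choose_model_direct(
                ref, observed, int(opts.get("n_closest", 500))
            )
            rows = [
                {
                    "scenario": s,
                    "posterior_probability": choice.posterior[s],
                    "ci_low": choice.ci[s][0],
                    "ci_high": choice.ci[s][1],
                    "is_true_scenario": s == truth_scenario,
                }
                for s in choice.posterior
            ]
            p = out / "abc_model_choice.tsv"
            _write(pd.DataFrame(rows), p)
            artifacts["abc_model_choice"] = p

            conf = abc_mod.evaluate_confidence(
                models, loci, int(opts.get("n_test_sets", 50)), ref,
                seed=seed + 1, n_closest=int(opts.get("n_closest", 500)),
                estimate=False,
            )
            crows = [
                {"scenario": s, "type_I": conf.type_I[s], "type_II": conf.type_II[s]}
                for s in conf.type_I
            ]
            p = out / "abc_confidence.tsv"
            _write(pd.DataFrame(crows), p)
            artifacts["abc_confidence"] = p
    except Exception:
        log.exception("stage failed; later stages skipped")
        raise
    finally:
        log.removeHandler(handler)
    return artifacts
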