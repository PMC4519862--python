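"""Synthetic study-like datasets with known ground truth.

The default :class:`StudyDesign` mirrors the crayfish survey design: 37
sampling populations (35 Chinese sites plus Saitama, Japan and Louisiana,
USA) with their published per-population sample sizes for a mitochondrial
control-region locus (291 sequences) and an X-linked nuclear intron locus
(192 sequences), and their sampling coordinates.  Populations are grouped
into the analysis units used for scenario testing: the entry-point trio
(LA, Sa, NJ = the three Nanjing sites combined) and the five Chinese
regions R1–R5.

Sequence lengths default to a desk-scale surrogate (400 bp control region,
250 bp intron) so the full pipeline runs in seconds; the study-scale
lengths are available via ``full_length=True``.

The scenario library ships the two best-supported invasion topologies —
an unsampled source founding Japan with serial introduction into Nanjing
(``cluster1_scenario5``), and Region I founding Regions II–IV with a serial
introduction from IV into V (``cluster2_scenario8``) — plus deliberately
contrasting alternatives per cluster (USA-origin serial chains, star
radiations) for model-choice power tests, and a whole-survey scenario
combining both layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalsim import (
    FoundingEvent,
    LocusDesign,
    ParameterDraw,
    Prior,
    ScenarioModel,
    sample_parameters,
    simulate_dataset,
)
from .seq_io import Alignment, PopulationMap, write_fasta

# population, longitude_deg, latitude_deg, n_control_region, n_intron, region
_TABLE1 = """\
SH	121.23	31.03	7	3	R5
NB	121.55	29.88	8	4	R5
JX	120.77	30.75	7	2	R5
XYc	118.50	33.00	7	6	R1
XYw	118.42	33.03	7	4	R1
WXb	120.28	31.52	9	6	R5
NT	120.87	32.02	7	6	R5
XG	118.75	32.08	8	7	R1
XBv	118.87	32.20	7	6	R1
BGt	118.82	32.17	7	7	R1
WX	120.30	31.57	6	7	R5
WJ	116.70	30.12	7	8	R4
MAS	118.50	31.55	8	6	R1
CJr	116.87	30.12	7	7	R4
CH	117.87	31.62	7	7	R1
HF	117.23	31.82	8	6	R1
DY	117.83	32.28	6	3	R1
SLt	116.22	29.75	8	5	R4
NBp	116.17	29.72	8	7	R4
PYL	116.43	28.87	7	2	R4
NCyl	116.12	28.52	8	3	R4
NHL	114.03	30.02	7	4	R3
YNL	112.20	30.00	8	6	R3
XT	113.40	30.30	8	6	R3
QJ	112.60	30.40	7	4	R3
LZL	114.00	30.00	6	2	R3
HHL	113.40	29.70	8	2	R3
CHL	112.10	30.30	7	6	R3
YJ	112.37	28.85	7	5	R3
NX	112.55	28.28	8	4	R3
DTL	113.02	29.30	6	2	R3
DTLs	113.13	29.35	8	4	R3
CQs	106.53	29.55	7	8	R2
ZX	108.03	30.28	6	7	R2
JY	104.55	30.38	6	6	R2
Sa	139.65	35.85	18	9	Sa
LA	-93.26	29.87	20	9	LA
"""

# Nanjing trio combined into the entry-point population for cluster-1 tests
NANJING_POPULATIONS = ("XG", "BGt", "XBv")


def table1_frame() -> pd.DataFrame:
    rows = [line.split("\t") for line in _TABLE1.strip().split("\n")]
    df = pd.DataFrame(
        rows,
        columns=["population", "longitude_deg", "latitude_deg",
                 "n_control_region", "n_intron", "region"],
    )
    for col in ("longitude_deg", "latitude_deg"):
        df[col] = df[col].astype(float)
    for col in ("n_control_region", "n_intron"):
        df[col] = df[col].astype(int)
    return df.set_index("population")


@dataclass
class StudyDesign:
    """Populations, per-locus sample sizes, grouping and coordinates."""

    table: pd.DataFrame = field(default_factory=table1_frame)
    control_length: int = 400
    intron_length: int = 250

    @classmethod
    def default(cls, full_length: bool = False) -> "StudyDesign":
        if full_length:
            return cls(control_length=970, intron_length=255)
        return cls()

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def coords(self) -> pd.DataFrame:
        return self.table[["latitude_deg", "longitude_deg"]]

    def regions(self) -> dict[str, str]:
        return dict(self.table["region"])

    def cluster1_groups(self) -> dict[str, str]:
        """population -> deme for the LA / Sa / NJ entry-point trio."""
        groups = {"LA": "LA", "Sa": "Sa"}
        groups.update({p: "NJ" for p in NANJING_POPULATIONS})
        return groups

    def deme_sample_sizes(
        self, groups: dict[str, str], locus_col: str
    ) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for pop, deme in groups.items():
            sizes[deme] = sizes.get(deme, 0) + int(self.table.loc[pop, locus_col])
        return sizes

    def locus_designs(
        self, groups: dict[str, str]
    ) -> list[LocusDesign]:
        return [
            LocusDesign(
                name="control_region",
                inheritance="mitochondrial",
                length=self.control_length,
                sample_sizes=self.deme_sample_sizes(groups, "n_control_region"),
            ),
            LocusDesign(
                name="propox_intron",
                inheritance="x_linked",
                length=self.intron_length,
                sample_sizes=self.deme_sample_sizes(groups, "n_intron"),
            ),
        ]


def _uniform_priors(names: dict[str, tuple[float, float]]) -> dict[str, Prior]:
    return {k: Prior(lo, hi) for k, (lo, hi) in names.items()}


def _scenario(
    name: str,
    populations: dict[str, str],
    sampled: list[str],
    events: list[tuple[str, str, str, str, str]],
    order: list[str],
) -> ScenarioModel:
    priors: dict[str, tuple[float, float]] = {}
    for p in populations.values():
        priors[p] = (1_000.0, 1_000_000.0)
    evs = []
    for t, src, tgt, nf, db in events:
        priors[t] = (1.0, 100.0)
        priors[nf] = (1.0, 10_000.0)
        priors[db] = (5.0, 25.0)
        evs.append(FoundingEvent(time=t, source=src, target=tgt,
                                 founder=nf, duration=db))
    return ScenarioModel(
        name=name, populations=populations, sampled=sampled,
        events=evs, priors=_uniform_priors(priors), order=order,
    )


def scenario_library() -> dict[str, ScenarioModel]:
    """Named invasion scenarios over the study's analysis units.

    Cluster-1 scenarios act on the LA / Sa / NJ trio (``anc`` is an
    unsampled ancestral source); cluster-2 scenarios act on regions R1–R5;
    ``full_study`` stitches both layers together for whole-survey synthesis.
    """
    lib: dict[str, ScenarioModel] = {}

    lib["cluster1_scenario5"] = _scenario(
        "cluster1_scenario5",
        populations={"LA": "N1", "Sa": "N2", "NJ": "N3", "anc": "N4"},
        sampled=["LA", "Sa", "NJ"],
        events=[
            ("t1", "Sa", "NJ", "Nf3", "db"),
            ("t2", "anc", "Sa", "Nf2", "db"),
            ("t3", "anc", "LA", "Nf1", "db"),
        ],
        order=["t1", "t2", "t3"],
    )
    lib["cluster1_usa_origin"] = _scenario(
        "cluster1_usa_origin",
        populations={"LA": "N1", "Sa": "N2", "NJ": "N3"},
        sampled=["LA", "Sa", "NJ"],
        events=[
            ("t1", "Sa", "NJ", "Nf3", "db"),
            ("t2", "LA", "Sa", "Nf2", "db"),
        ],
        order=["t1", "t2"],
    )
    lib["cluster1_star"] = _scenario(
        "cluster1_star",
        populations={"LA": "N1", "Sa": "N2", "NJ": "N3", "anc": "N4"},
        sampled=["LA", "Sa", "NJ"],
        events=[
            ("t1", "anc", "NJ", "Nf3", "db"),
            ("t2", "anc", "Sa", "Nf2", "db"),
            ("t3", "anc", "LA", "Nf1", "db"),
        ],
        order=["t1", "t2", "t3"],
    )

    lib["cluster2_scenario8"] = _scenario(
        "cluster2_scenario8",
        populations={"R1": "N1", "R2": "N2", "R3": "N3", "R4": "N4", "R5": "N5"},
        sampled=["R1", "R2", "R3", "R4", "R5"],
        events=[
            ("t1", "R4", "R5", "Nf5", "db"),
            ("t2", "R1", "R4", "Nf4", "db"),
            ("t3", "R1", "R3", "Nf3", "db"),
            ("t4", "R1", "R2", "Nf2", "db"),
        ],
        order=["t1", "t2", "t3", "t4"],
    )
    lib["cluster2_serial"] = _scenario(
        "cluster2_serial",
        populations={"R1": "N1", "R2": "N2", "R3": "N3", "R4": "N4", "R5": "N5"},
        sampled=["R1", "R2", "R3", "R4", "R5"],
        events=[
            ("t1", "R4", "R5", "Nf5", "db"),
            ("t2", "R3", "R4", "Nf4", "db"),
            ("t3", "R2", "R3", "Nf3", "db"),
            ("t4", "R1", "R2", "Nf2", "db"),
        ],
        order=["t1", "t2", "t3", "t4"],
    )
    lib["cluster2_star"] = _scenario(
        "cluster2_star",
        populations={"R1": "N1", "R2": "N2", "R3": "N3", "R4": "N4", "R5": "N5"},
        sampled=["R1", "R2", "R3", "R4", "R5"],
        events=[
            ("t1", "R1", "R5", "Nf5", "db"),
            ("t2", "R1", "R4", "Nf4", "db"),
            ("t3", "R1", "R3", "Nf3", "db"),
            ("t4", "R1", "R2", "Nf2", "db"),
        ],
        order=["t1", "t2", "t3", "t4"],
    )

    lib["full_study"] = _scenario(
        "full_study",
        populations={
            "LA": "NL", "Sa": "NS", "anc": "NA",
            "R1": "N1", "R2": "N2", "R3": "N3", "R4": "N4", "R5": "N5",
        },
        sampled=["LA", "Sa", "R1", "R2", "R3", "R4", "R5"],
        events=[
            ("t1", "R4", "R5", "Nf5", "db"),
            ("t2", "R1", "R4", "Nf4", "db"),
            ("t3", "R1", "R3", "Nf3", "db"),
            ("t4", "R1", "R2", "Nf2", "db"),
            ("t5", "Sa", "R1", "Nf1", "db"),
            ("t6", "anc", "Sa", "NfS", "db"),
            ("t7", "anc", "LA", "NfL", "db"),
        ],
        order=["t1", "t2", "t3", "t4", "t5", "t6", "t7"],
    )
    return lib


def groups_for_scenario(design: StudyDesign, model: ScenarioModel) -> dict[str, str]:
    """Map design populations onto the scenario's sampled demes."""
    demes = set(model.sampled)
    if demes == {"LA", "Sa", "NJ"}:
        return design.cluster1_groups()
    groups: dict[str, str] = {}
    regions = design.regions()
    for pop in design.populations:
        deme = regions[pop] if regions[pop] in demes else pop
        if deme in demes:
            groups[pop] = deme
    return groups


@dataclass
class GeneratedStudy:
    alignments: dict[str, Alignment]
    popmap: PopulationMap
    coords: pd.DataFrame
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def generate_study(
    design: StudyDesign,
    scenario: str | ScenarioModel,
    seed: int,
    params: ParameterDraw | None = None,
    out_dir: str | Path | None = None,
) -> GeneratedStudy:
    """Simulate a full study-like dataset and (optionally) write it to disk.

    Sequences are simulated at the level of the scenario's demes, then rows
    are attributed to the member sampling populations at their designed
    per-population sample sizes (lineages within a deme are exchangeable, so
    the attribution is free).  Writes per-locus FASTA, a popmap TSV, a
    coordinates TSV and a machine-readable JSON truth file (scenario,
    parameter values, seed); the same seed always reproduces byte-identical
    files.
    """
    model = scenario_library()[scenario] if isinstance(scenario, str) else scenario
    rng = np.random.default_rng(seed)
    groups = groups_for_scenario(design, model)
    loci = design.locus_designs(groups)
    if params is None:
        params = sample_parameters(model, rng)
    ds = simulate_dataset(model, params, loci, rng)

    # attribute deme rows to member populations in design order
    locus_cols = {"control_region": "n_control_region",
                  "propox_intron": "n_intron"}
    alignments: dict[str, Alignment] = {}
    assignments: dict[str, str] = {}
    for locus in loci:
        mat = ds.matrices[locus.name]
        deme_rows: dict[str, list[int]] = {}
        for i, deme in enumerate(ds.populations[locus.name]):
            deme_rows.setdefault(deme, []).append(i)
        seqs = []
        col = locus_cols[locus.name]
        for pop in design.populations:
            if pop not in groups:
                continue
            deme = groups[pop]
            n_pop = int(design.table.loc[pop, col])
            rows = [deme_rows[deme].pop() for _ in range(n_pop)]
            for idx, row in enumerate(rows, 1):
                sid = f"{pop}_{locus.name}_{idx}"
                seqs.append((sid, mat[row].tobytes().decode()))
                assignments[sid] = pop
        alignments[locus.name] = Alignment(locus.name, locus.inheritance, seqs)

    regions = design.regions()
    popmap = PopulationMap(assignments,
                           {p: regions[p] for p in design.populations
                            if p in groups})
    used = [p for p in design.populations if p in groups]
    coords = design.coords().loc[used]
    truth = {
        "scenario": model.name,
        "seed": seed,
        "parameters": dict(params.values),
        "mu": params.mu,
        "kappa": params.kappa,
        "p_inv": params.p_inv,
        "n_sequences": {loc.name: alignments[loc.name].n for loc in loci},
    }

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in alignments.items():
            paths[f"fasta_{name}"] = out / f"{name}.fasta"
            write_fasta(aln, paths[f"fasta_{name}"])
        pm = pd.DataFrame(
            {
                "sample_id": list(assignments),
                "population": [assignments[s] for s in assignments],
            }
        )
        pm["region"] = [regions[p] for p in pm["population"]]
        paths["popmap"] = out / "popmap.tsv"
        pm.to_csv(paths["popmap"], sep="\t", index=False)
        cdf = coords.reset_index()
        cdf = cdf[["population", "latitude_deg", "longitude_deg"]]
        paths["coords"] = out / "coords.tsv"
        cdf.to_csv(paths["coords"], sep="\t", index=False)
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return GeneratedStudy(
        alignments=alignments, popmap=popmap, coords=coords,
        truth=truth, paths=paths,
    )
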