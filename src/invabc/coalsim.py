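"""Coalescent simulation of invasion scenarios.

A :class:`ScenarioModel` declares populations (sampled or unsampled
"ghost" sources), founding events and parameter priors.  A founding event
``(t, source, target, Nf, db)`` means, forward in time: the target
population was founded from the source ``t`` generations ago, went through
a founder bottleneck of effective size ``Nf`` lasting ``db`` generations,
and has had its stable effective size ``N`` since generation ``t - db``.
Backward in time the simulator runs a structured coalescent with
piecewise-constant sizes: target lineages coalesce at the stable size for
ages in ``[0, t - db)``, at the founder size in ``[t - db, t)``, and merge
into the source at age ``t``.

Sizes are expressed as the paper-facing parameter ``N`` (individuals); the
number of gene copies behind a locus follows its inheritance:
``N/2`` (mitochondrial), ``3N/2`` (X-linked), ``2N`` (autosomal).

Mutation is finite-sites Kimura two-parameter: Poisson events at rate
``mu`` per variable site per generation, transitions chosen with
probability ``kappa / (kappa + 2)``; a fixed fraction ``p_inv`` of sites
(default 10%) is drawn once per dataset and never mutates.  Multiple hits
are allowed.  Times are generations throughout; no recombination and no
two-source admixture events (the scenario DSL is divergence-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .seq_io import COPY_SCALING, Alignment, InputError, PopulationMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# K2P partners: transition target, and the two transversion targets per base
_TRANSITION = {ord("A"): ord("G"), ord("G"): ord("A"),
               ord("C"): ord("T"), ord("T"): ord("C")}
_TRANSVERSIONS = {ord("A"): (ord("C"), ord("T")), ord("G"): (ord("C"), ord("T")),
                  ord("C"): (ord("A"), ord("G")), ord("T"): (ord("A"), ord("G"))}

DEFAULT_DEMOGRAPHIC_PRIORS = {
    "t": (1.0, 100.0),
    "db": (5.0, 25.0),
    "N": (1_000.0, 1_000_000.0),
    "Nf": (1.0, 10_000.0),
}
# sequence mutation priors: log-uniform rate, uniform ts/tv ratio
DEFAULT_MUTATION_PRIORS = {"mu": (1e-9, 1e-7), "kappa": (0.05, 20.0)}
DEFAULT_P_INV = 0.10


@dataclass
class Prior:
    """Uniform (or log-uniform) prior over a closed interval."""

    low: float
    high: float
    log: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass
class FoundingEvent:
    time: str        # parameter name, generations ago
    source: str
    target: str
    founder: str     # parameter name for Nf
    duration: str    # parameter name for db


@dataclass
class ScenarioModel:
    """A demographic invasion scenario with priors.

    ``populations`` maps population name → stable-size parameter name;
    ``sampled`` lists the populations that appear in datasets; every other
    population is a ghost.  ``order`` lists parameter names that must be
    strictly increasing in any draw (e.g. event times).
    """

    name: str
    populations: dict[str, str]
    sampled: list[str]
    events: list[FoundingEvent]
    priors: dict[str, Prior]
    order: list[str] = field(default_factory=list)
    p_inv: float = DEFAULT_P_INV

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        pops = set(self.populations)
        for s in self.sampled:
            if s not in pops:
                raise InputError(f"sampled population {s!r} not declared")
        founded: set[str] = set()
        for ev in self.events:
            for p in (ev.source, ev.target):
                if p not in pops:
                    raise InputError(f"event references unknown population {p!r}")
            if ev.target in founded:
                raise InputError(f"population {ev.target!r} founded twice")
            founded.add(ev.target)
        # cycle check: following target -> source must terminate at a root
        src_of = {ev.target: ev.source for ev in self.events}
        for start in pops:
            seen = {start}
            cur = start
            while cur in src_of:
                cur = src_of[cur]
                if cur in seen:
                    raise InputError(f"cycle in founding events at {cur!r}")
                seen.add(cur)
        # common ancestry: union of merge edges must connect all populations
        parent = {p: p for p in pops}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ev in self.events:
            parent[find(ev.source)] = find(ev.target)
        roots = {find(p) for p in pops}
        if len(roots) != 1:
            raise InputError(
                "sampled populations do not share a common ancestor "
                f"(disconnected groups: {len(roots)})"
            )
        for name in self.order:
            if name not in self.priors:
                raise InputError(f"ordered parameter {name!r} has no prior")
        missing = [
            p for ev in self.events
            for p in (ev.time, ev.founder, ev.duration)
            if p not in self.priors
        ]
        missing += [v for v in self.populations.values() if v not in self.priors]
        if missing:
            raise InputError(f"parameters without priors: {sorted(set(missing))}")

    @property
    def ghosts(self) -> list[str]:
        return [p for p in self.populations if p not in self.sampled]

    @property
    def demographic_parameters(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            for p in (ev.time, ev.founder, ev.duration):
                seen.setdefault(p, None)
        for v in self.populations.values():
            seen.setdefault(v, None)
        return list(seen)


@dataclass
class ParameterDraw:
    values: dict[str, float]     # demographic parameters by name
    mu: float                    # per variable site per generation
    kappa: float                 # transition/transversion rate ratio
    p_inv: float

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class MutationModel:
    mu: float
    kappa: float
    p_inv: float
    L: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_inv < 1.0):
            raise InputError("p_inv must be in [0, 1)")


@dataclass
class LocusDesign:
    name: str
    inheritance: str
    length: int
    sample_sizes: dict[str, int]   # sampled population -> sequences


@dataclass
class Genealogy:
    """A coalescent tree: ``parent[i]`` and node ``time`` in generations.

    Leaves are nodes ``0..n-1`` in the order of ``leaf_populations``; the
    root has parent ``-1``.
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_populations: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_populations)

    def total_branch_length(self) -> float:
        bl = self.time[self.parent] - self.time
        return float(np.sum(bl[self.parent >= 0]))


def parse_scenario(text: str) -> ScenarioModel:
    """Parse a YAML scenario description into a validated ScenarioModel.

    Expected keys: ``name``, ``populations`` (name → size parameter),
    ``sampled`` (list), ``events`` (list of mappings with time/source/
    target/founder/duration), ``priors`` (parameter → {low, high, log}),
    optional ``order`` and ``p_inv``.  Priors omitted for a parameter fall
    back to the study defaults based on its name prefix (t/db/N/Nf).
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InputError(f"bad scenario config: {exc}") from exc
    if not isinstance(doc, dict):
        raise InputError("scenario config must be a mapping")
    events = [
        FoundingEvent(
            time=str(e["time"]), source=str(e["source"]), target=str(e["target"]),
            founder=str(e["founder"]), duration=str(e["duration"]),
        )
        for e in doc.get("events", [])
    ]
    priors = {
        k: Prior(float(v["low"]), float(v["high"]), bool(v.get("log", False)))
        for k, v in doc.get("priors", {}).items()
    }
    populations = {str(k): str(v) for k, v in doc["populations"].items()}
    # fill defaults for any parameter the config leaves out
    all_params = {v for v in populations.values()}
    for ev in events:
        all_params.update((ev.time, ev.founder, ev.duration))
    for p in sorted(all_params - set(priors)):
        for prefix in ("Nf", "db", "N", "t"):
            if p.startswith(prefix):
                lo, hi = DEFAULT_DEMOGRAPHIC_PRIORS[prefix]
                priors[p] = Prior(lo, hi)
                break
        else:
            raise InputError(f"no prior given or derivable for {p!r}")
    return ScenarioModel(
        name=str(doc.get("name", "scenario")),
        populations=populations,
        sampled=[str(s) for s in doc["sampled"]],
        events=events,
        priors=priors,
        order=[str(o) for o in doc.get("order", [])],
        p_inv=float(doc.get("p_inv", DEFAULT_P_INV)),
    )


def sample_parameters(
    model: ScenarioModel,
    rng: np.random.Generator,
    mutation_priors: Mapping[str, tuple[float, float]] | None = None,
    max_attempts: int = 100_000,
) -> ParameterDraw:
    """Draw demographic + mutation parameters from the scenario priors.

    Ordering constraints (``model.order`` strictly increasing) are enforced
    by rejection; an error is raised if no draw satisfies them within
    ``max_attempts`` rounds (infeasible constraint region).
    """
    mp = dict(DEFAULT_MUTATION_PRIORS)
    if mutation_priors:
        mp.update(mutation_priors)
    for _ in range(max_attempts):
        values = {name: prior.sample(rng) for name, prior in model.priors.items()}
        ordered = [values[p] for p in model.order]
        if all(a < b for a, b in zip(ordered, ordered[1:])):
            mu = float(np.exp(rng.uniform(*np.log(mp["mu"]))))
            kappa = float(rng.uniform(*mp["kappa"]))
            return ParameterDraw(values=values, mu=mu, kappa=kappa,
                                 p_inv=model.p_inv)
    raise InputError(
        f"could not satisfy ordering constraints {model.order} after "
        f"{max_attempts} attempts"
    )


def simulate_genealogy(
    model: ScenarioModel,
    draw: ParameterDraw,
    sample_sizes: Mapping[str, int],
    inheritance: str,
    rng: np.random.Generator,
) -> Genealogy:
    """Backward-in-time structured coalescent under the scenario.

    ``sample_sizes`` gives gene copies sampled per sampled population.
    Within each epoch every population with k lineages coalesces at rate
    k(k-1)/(2G) per generation, G being its current gene-copy number; at a
    founding event's age all target lineages move to the source.
    """
    scale = COPY_SCALING[inheritance]
    size_of = {
        pop: scale * draw[param] for pop, param in model.populations.items()
    }
    events = sorted(model.events, key=lambda ev: draw[ev.time])
    # piecewise sizes: (start_age, end_age, pop, size) for bottleneck windows
    bottlenecks = []
    for ev in events:
        t = draw[ev.time]
        db = min(draw[ev.duration], t)  # bottleneck cannot predate the present
        bottlenecks.append((t - db, t, ev.target, scale * draw[ev.founder]))

    def pop_size(pop: str, age: float) -> float:
        for start, end, p, size in bottlenecks:
            if p == pop and start <= age < end:
                return max(size, 1.0)
        return max(size_of[pop], 1.0)

    leaf_pops: list[str] = []
    for pop in model.sampled:
        leaf_pops.extend([pop] * int(sample_sizes.get(pop, 0)))
    n = len(leaf_pops)
    if n < 1:
        raise InputError("no samples requested")

    total_nodes = 2 * n - 1
    parent = np.full(total_nodes, -1, dtype=np.int64)
    time = np.zeros(total_nodes, dtype=float)
    next_node = n

    lineages: dict[str, list[int]] = {p: [] for p in model.populations}
    for i, pop in enumerate(leaf_pops):
        lineages[pop].append(i)

    breakpoints = sorted(
        {draw[ev.time] for ev in events}
        | {start for start, _, _, _ in bottlenecks if start > 0}
    )
    merge_at = {draw[ev.time]: ev for ev in events}

    age = 0.0
    bp_iter = iter(breakpoints + [math.inf])
    next_bp = next(bp_iter)
    active = lambda: sum(len(v) for v in lineages.values())
    while active() > 1:
        rates = {
            p: len(v) * (len(v) - 1) / (2.0 * pop_size(p, age))
            for p, v in lineages.items()
            if len(v) >= 2
        }
        total_rate = sum(rates.values())
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = math.inf
        if age + wait >= next_bp:
            age = next_bp
            if age in merge_at:
                ev = merge_at[age]
                lineages[ev.source].extend(lineages[ev.target])
                lineages[ev.target] = []
            next_bp = next(bp_iter)
            continue
        age += wait
        u = rng.uniform(0, total_rate)
        acc = 0.0
        for p, r in rates.items():
            acc += r
            if u < acc:
                pool = lineages[p]
                i, j = rng.choice(len(pool), size=2, replace=False)
                a, b = pool[int(i)], pool[int(j)]
                node = next_node
                next_node += 1
                parent[a] = parent[b] = node
                time[node] = age
                pool.remove(a)
                pool.remove(b)
                pool.append(node)
                break
    return Genealogy(parent=parent, time=time, leaf_populations=leaf_pops)


def apply_mutations(
    tree: Genealogy,
    mm: MutationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop K2P mutations on the genealogy; return an (n, L) uint8 matrix.

    ``floor(p_inv * L)`` sites, chosen once, never mutate.  Mutations are
    Poisson at rate ``mu`` per variable site per generation on every branch;
    each picks a uniform variable site and mutates the current base with
    transition probability ``kappa / (kappa + 2)``.
    """
    L = mm.L
    n_inv = int(math.floor(mm.p_inv * L))
    sites = rng.permutation(L)
    var_sites = np.sort(sites[n_inv:])
    n_var = var_sites.size

    n = tree.n_leaves
    total = tree.parent.size
    children: list[list[int]] = [[] for _ in range(total)]
    root = -1
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children[p].append(i)
        else:
            root = i

    p_ts = mm.kappa / (mm.kappa + 2.0)
    seqs = np.empty((total, L), dtype=np.uint8)
    seqs[root] = rng.choice(_BASES, size=L)
    # pre-order traversal from the root, mutating copies of the parent state
    stack = children[root][:]
    while stack:
        node = stack.pop()
        seq = seqs[tree.parent[node]].copy()
        branch = tree.time[tree.parent[node]] - tree.time[node]
        if n_var and branch > 0:
            n_mut = rng.poisson(mm.mu * n_var * branch)
            for _ in range(n_mut):
                site = int(var_sites[rng.integers(n_var)])
                base = int(seq[site])
                if rng.random() < p_ts:
                    seq[site] = _TRANSITION[base]
                else:
                    a, b = _TRANSVERSIONS[base]
                    seq[site] = a if rng.random() < 0.5 else b
        seqs[node] = seq
        stack.extend(children[node])
    return seqs[:n]


@dataclass
class SimulatedDataset:
    """Per-locus sequence matrices plus the shared population labels."""

    matrices: dict[str, np.ndarray]             # locus -> (n, L) uint8
    populations: dict[str, list[str]]           # locus -> per-row labels
    design: list[LocusDesign]

    def to_alignments(self, prefix: str = "") -> tuple[dict[str, Alignment], PopulationMap]:
        alignments: dict[str, Alignment] = {}
        assignments: dict[str, str] = {}
        for locus in self.design:
            mat = self.matrices[locus.name]
            labels = self.populations[locus.name]
            seqs = []
            counter: dict[str, int] = {}
            for row, pop in zip(mat, labels):
                counter[pop] = counter.get(pop, 0) + 1
                sid = f"{prefix}{pop}_{locus.name}_{counter[pop]}"
                seqs.append((sid, row.tobytes().decode()))
                assignments[sid] = pop
            alignments[locus.name] = Alignment(locus.name, locus.inheritance, seqs)
        return alignments, PopulationMap(assignments)


def simulate_dataset(
    model: ScenarioModel,
    draw: ParameterDraw,
    design: Sequence[LocusDesign],
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Simulate all loci under one demographic draw.

    Genealogies are independent across loci (free recombination between
    loci, none within) but share the same event times and sizes.
    """
    matrices: dict[str, np.ndarray] = {}
    pops: dict[str, list[str]] = {}
    for locus in design:
        tree = simulate_genealogy(
            model, draw, locus.sample_sizes, locus.inheritance, rng
        )
        mm = MutationModel(mu=draw.mu, kappa=draw.kappa, p_inv=draw.p_inv,
                           L=locus.length)
        matrices[locus.name] = apply_mutations(tree, mm, rng)
        pops[locus.name] = list(tree.leaf_populations)
    return SimulatedDataset(matrices=matrices, populations=pops,
                            design=list(design))
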