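# invabc

Invasion-history inference from multi-locus DNA sequence surveys:
descriptive population genetics, statistical-parsimony haplotype networks,
and Approximate Bayesian Computation (ABC) scenario testing, with a
coalescent simulator for declarative invasion scenarios and a synthetic
study generator for end-to-end validation.

The package is aimed at molecular ecologists reconstructing how an
introduced species spread: which foreign population seeded the invasion,
whether an unsampled ("ghost") source was involved, and along which routes
the species expanded.  Its reference design is a survey of the red swamp
crayfish (*Procambarus clarkii*) across 37 sampling populations — 35 in
China plus one each in Japan and the USA — typed at a mitochondrial
control-region locus and an X-linked nuclear intron, but every component
accepts arbitrary alignments, population maps and scenario definitions.

## What it computes

**Diversity and neutrality.** Haplotype diversity
`Hd = n(1 − Σp̂ᵢ²)/(n−1)` with Nei's sampling variance; mean pairwise
differences `k` and nucleotide diversity `π = k / L`; segregating sites and
site classes (singleton, parsimony-informative of 2 or 3 variants, gap
sites); pairwise distances under p, JC69, K2P
(`d = −½ln(1−2P−Q) − ¼ln(1−2Q)`) and a composite-likelihood Tamura–Nei
mode; Tajima's `D`, Fu & Li's `D*`, and Fu's `Fs` from the Ewens sampling
formula (`S′ = P(K ≥ k_obs | θ̂_π)`, `Fs = ln(S′/(1−S′))`) with a
coalescent-simulation p-value.

**Structure.** Two-level AMOVA (Φ_ST with permutation p-values) and
isolation by distance: pairwise-population Φ_ST against great-circle
distance under a Mantel permutation test.

**Networks.** Statistical parsimony haplotype networks at the 95%
connection limit, retaining equal-length alternative paths as loops
(evidence of homoplasy), with frequency-plus-connectivity ancestral
("outgroup") weights per subnetwork.

**ABC scenario testing.** A backward-in-time structured coalescent over
declarative scenarios — populations (sampled or ghost), founding events
with time `t`, founder size `Nf` and bottleneck duration `db`, gene-copy
scaling N/2 / 3N/2 / 2N for mitochondrial / X-linked / autosomal loci,
finite-sites K2P mutation with 10% invariant sites — feeding a reference
table of summary statistics (haplotype counts, segregating sites, mean
pairwise differences within and between populations).  Model choice is the
direct estimate (scenario share among the closest simulations under
MAD-normalized Euclidean distance); parameter posteriors use local linear
regression on the log scale; confidence evaluation reports type I/II error
rates and relative bias/RMSE from pseudo-observed datasets.

## Worked example

Generate a survey-scale synthetic study under the combined invasion
scenario (ghost source → Japan → Nanjing → serial expansion through five
Chinese regions) with known parameters, then run the descriptive stages:

```python
from invabc import diversity, network, structure
from invabc.coalsim import ParameterDraw
from invabc.seq_io import collapse_haplotypes
from invabc.synthetic_data import StudyDesign, generate_study

design = StudyDesign.default()
values = {"NL": 100000.0, "NS": 50000.0, "NA": 150000.0,
          "N1": 40000.0, "N2": 20000.0, "N3": 30000.0, "N4": 30000.0,
          "N5": 30000.0,
          "t1": 10.0, "t2": 20.0, "t3": 30.0, "t4": 40.0, "t5": 55.0,
          "t6": 70.0, "t7": 85.0,
          "Nf1": 500.0, "Nf2": 30.0, "Nf3": 30.0, "Nf4": 30.0, "Nf5": 30.0,
          "NfS": 100.0, "NfL": 5000.0, "db": 15.0}
params = ParameterDraw(values=values, mu=5e-7, kappa=2.0, p_inv=0.1)
study = generate_study(design, "full_study", seed=42, params=params)

aln = study.alignments["control_region"]
rep = diversity.diversity_report(aln)
print(f"n={rep.n}  H={rep.H}  Hd={rep.Hd:.3f}  pi={rep.pi:.5f}  "
      f"k={rep.k:.2f}  S={rep.S}")
print(f"Tajima D = {diversity.tajima_D(aln):.3f}")
fs, p = diversity.fu_Fs(aln, n_null_sims=200, seed=1)
print(f"Fu's Fs = {fs:.3f} (p = {p:.3f})")

amova = structure.amova_two_level(aln, study.popmap, n_perm=999, seed=1)
print(f"AMOVA: {amova.pct_among:.2f}% among / {amova.pct_within:.2f}% "
      f"within, Phi_ST={amova.Phi_ST:.3f}, p={amova.p_value:.3f}")
ibd = structure.isolation_by_distance(aln, study.popmap, study.coords,
                                      n_perm=999, seed=1)
print(f"Mantel: r={ibd.r:.4f}, p={ibd.p:.4f}")

haps = collapse_haplotypes(aln, study.popmap)
limit = network.connection_limit(int(aln.complete_sites().sum()), 0.95)
net = network.build_networks(haps, limit)
print(f"networks: limit={limit} steps, {net.n_components} component(s)")
```

prints

```
n=291  H=18  Hd=0.769  pi=0.05083  k=20.33  S=110
Tajima D = 0.468
Fu's Fs = 29.131 (p = 0.980)
AMOVA: 36.90% among / 63.10% within, Phi_ST=0.369, p=0.001
Mantel: r=-0.0870, p=0.4880
networks: limit=6 steps, 7 component(s)
```

Reading the numbers: 291 control-region sequences collapse to 18
haplotypes; the repeated strong founder events (`Nf = 30` for the Chinese
regions) leave a significant share of molecular variance among populations
(Φ_ST = 0.37, permutation p = 0.001) while human-mediated jump dispersal in
the scenario leaves no isolation-by-distance signal (Mantel r ≈ −0.09,
p = 0.49).  The positive Fu's `Fs` reflects a deficit of haplotypes
relative to the pairwise diversity — the signature of founder bottlenecks
rather than expansion.  At the 95% parsimony connection limit of 6 steps
the haplotypes split into 7 subnetworks.

The same study can then be fed to the ABC layer
(`invabc.abc.build_reference_table`, `choose_model_direct`,
`evaluate_confidence`) to ask which scenario generated it; see
`docs/methods.md` for the machinery and its measured calibration, including
the deliberate finding that under the survey's own priors the competing
invasion topologies are close to statistically indistinguishable.

A command-line interface mirrors the modules:

```sh
invabc synth generate --design table1 --scenario cluster1_scenario5 \
    --seed 42 --out data/
invabc stats --fasta data/control_region.fasta --popmap data/popmap.tsv \
    --coords data/coords.tsv --seed 1 --out diversity.tsv
invabc pipeline run --config run.yaml
```

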