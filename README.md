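# pcnmd

Post-simulation analysis of protein–protein complexes: **p**rotein
**c**ontact **n**etworks plus **MD** trajectory geometry and binding-energy
bookkeeping.

Molecular-dynamics studies of drug–target complexes (the motivating case is
antibody/receptor traps binding a growth-factor dimer, e.g. anti-VEGF agents
on VEGFA) end with a stack of standard analyses: was the trajectory
equilibrated and well sampled, how do the partners move, which residues hold
the interface together, and how do the energy terms of an MM-PBSA
calculation combine?  `pcnmd` implements that analysis layer as a reusable
library + CLI, working from plain single/multi-model PDB files and TSV
energy tables, with a synthetic-fixture generator so every operation is
testable without downloading any structure.

## What it computes

**Contact networks.**  Each structure (or frame) becomes an undirected,
unweighted graph on residue α-carbons with an edge when
4 Å ≤ |Cα_i − Cα_j| ≤ 8 Å and the residues are not sequence-adjacent — the
van-der-Waals packing network.  Per network: the average degree *adeg* =
2E/N, the average shortest path *asp*, the graph energy E = Σ|λ_i| of the
adjacency spectrum, and the Eisenberg–McLachlan solvation free energy
dG_solv = Σ Δσ(class)·ASA.  Descriptor series over a trajectory feed a
Pearson correlation/equilibration report: a descriptor with a significant
correlation against time is flagged as drifting.

**Module partitioning.**  Spectral clustering (symmetric normalised
Laplacian embedding + seeded k-means) splits the network into functional
modules; the partition color map lays clusters along the sequence and marks
"whiskers" — residues whose cluster differs from both sequence neighbours,
the signature of a long-range contact.

**Trajectory geometry.**  Kabsch superposition (proper rotations only),
RMSD and split RMSD (each binding partner fit to its own reference),
per-residue RMSF, covariance PCA (essential dynamics), and the cosine
content c_i = (2/T)(∫cos(iπt/T)p(t)dt)²/∫p²dt of the leading projections;
c_i ≥ 0.5 flags diffusive, under-sampled components.

**Interface statistics.**  Atom-pair contact counts between two groups per
frame (3.5 Å cutoff, mean ± sd over the trajectory) and geometric
hydrogen-bond detection (donor–acceptor ≤ 3.5 Å, D–H···A deviation from
linearity ≤ 30°) with per-bond occupancy.

**Energy ledger.**  ΔE_binding = E_complex − (E_receptor + E_ligand),
combined per term over externally supplied MM-PBSA tables; the apolar
solvation term G_apolar = γ·SASA (γ = 0.022 kJ/mol·Å², Shrake–Rupley SASA
with Bondi radii and a 1.4 Å probe) is computed natively; per-residue
decomposition energies are painted into the PDB b-factor field for
hot-spot visualisation.  Entropy is not modelled, hence ΔE, not ΔG.

## Worked example

```python
import numpy as np
import pcnmd as p

spec = p.FixtureSpec(kind="two_domain", n_residues=40, motion="gaussian",
                     n_frames=100, noise_sigma=0.15, seed=42)
base = p.make_backbone(spec)          # two helical bundles + one linker
ens = p.make_ensemble(base, spec)     # 100 frames, 10 ps spacing

net = p.build_contact_network(base)
d = p.network_descriptors(net, base)
print(f"nodes={d.n_nodes} edges={d.n_edges} adeg={d.adeg:.2f} "
      f"asp={d.asp:.2f} E={d.graph_energy:.2f} dG_solv={d.dg_solv:.2f} kcal/mol")

part = p.spectral_partition(net, k=2, seed=0)
print("cluster sizes:", np.bincount(part.labels), "whiskers:", sorted(part.whiskers))

series = p.descriptor_series(ens, include_dg_solv=False)
verdict = p.equilibration_check(
    p.correlation_matrix(series[["time_ps", "adeg", "asp", "E"]]))
print({v: verdict.verdicts[v] for v in verdict.verdicts})

result = p.pca(ens, p.select(base, "name CA"))
print(f"PC1 variance fraction {result.variance_fraction[0]:.3f}, "
      f"cosine content {result.cosine_content[0]:.3f}")

be = p.binding_energy(
    p.EnergyTerms({"E_vdw": -4.8, "G_apolar": -5.2}),
    p.EnergyTerms({"E_vdw": -2.0, "G_apolar": -2.5}),
    p.EnergyTerms({"E_vdw": -1.0, "G_apolar": -1.5}),
)
print("per-term:", be.per_term, f"dE_binding = {be.total:.1f} kJ/mol")
```

Output:

```
nodes=40 edges=100 adeg=5.00 asp=2.24 E=64.39 dG_solv=27.16 kcal/mol
cluster sizes: [20 20] whiskers: []
{'adeg': 'stationary', 'asp': 'stationary', 'E': 'stationary'}
PC1 variance fraction 0.039, cosine content 0.010
per-term: {'E_vdw': -1.7999999999999998, 'G_apolar': -1.2000000000000002} dE_binding = -3.0 kJ/mol
```

Reading it: the two 20-residue domains are cleanly recovered as the two
clusters with no whiskers (the fixture has a single inter-domain link); the
descriptor series shows no drift, so the window behaves like a relative
conformational minimum; iid thermal noise spreads variance across many PCs
(PC1 carries only 4%) and its cosine content is far below the 0.5
diffusion flag; the energy ledger combines to −3.0 kJ/mol, the sum of its
per-term differences.

The same analyses are available from the shell, e.g.

```sh
pcnmd fixtures make --kind two_domain --n-residues 40 --motion gaussian \
      --n-frames 100 --noise-sigma 0.15 --seed 42 --out traj.pdb
pcnmd net descriptors --traj traj.pdb --no-dg-solv --out descriptors.tsv
pcnmd net correlate --descriptors descriptors.tsv
pcnmd traj pca --traj traj.pdb --out-prefix pca
pcnmd report --traj traj.pdb --groupA "resid 1-20" --groupB "resid 21-40" --k 2
```

On real data, point `--pdb/--traj` at a crystal structure or a multi-model
trajectory export; `pcnmd.datasets.fetch_pdb("1CZ8")` retrieves the
canonical worked-example structure (ranibizumab/VEGFA) when the network is
available — its VEGFA dimer chains V+W give a 200-node contact network.

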