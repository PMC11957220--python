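# chaostopo

Topology-regulated coupled chaotic oscillators for feature engineering on
point clouds, multichannel signals and protein structures.

## The idea

Many prediction problems hand you objects with pairwise structure — residues
of a protein with their Cα geometry, EEG channels with their correlations,
cells or images with distances in an embedding — and ask for per-object or
per-sample predictions.  `chaostopo` turns that pairwise structure into
dynamics: every object becomes a 3-variable chaotic oscillator (Lorenz or
Rössler), and objects are coupled diffusively through their interaction
network,

```
dx_i/dt = F(x_i) + ε Σ_j G_ij Γ x_j ,
```

where `G` is a symmetric zero-row-sum coupling matrix, `ε` the coupling
strength and `Γ` a 3×3 linking matrix (identity by default).  Because the
coupling vanishes on the synchronization manifold, strong coupling on a
connected graph synchronizes the ensemble; weak or absent coupling leaves
the nodes independently chaotic.  Between those extremes, *how* each node
approaches (or resists) synchronization encodes its structural role.

The multiscale part comes from a persistent-Laplacian filtration: the
weighted interaction matrix (distance kernel or |Pearson| correlation) is
thresholded at `p` accumulation levels between its smallest and largest
off-diagonal weight, yielding a nested family of coupling graphs
`L¹ ⊇ L² ⊇ … ⊇ L^p = ∅`.  Each level gives one coupled chaotic system;
summary statistics (mean, std, min, max, median, skewness, kurtosis) of the
post-transient trajectories, concatenated across levels, form a fixed-length
feature vector per node that feeds ordinary classifiers (KNN / random
forest / gradient boosting) or a per-protein linear regression for
B-factor-style flexibility prediction.

The package also implements simplicial persistent Laplacians on
Vietoris–Rips complexes: for a nested pair `K_t ⊆ K_{t+p}`,

```
L_q^{t,p} = B_{q+1}^{t,p} (B_{q+1}^{t,p})ᵀ + (B_qᵗ)ᵀ B_qᵗ ,
```

whose kernel dimension is the persistent Betti number β_q^{t,p} and whose
smallest nonzero eigenvalue tracks homotopic shape evolution along the
filtration.

## Worked example

Per-residue flexibility on a synthetic protein-like chain with a planted
profile (high mobility at loosely packed termini, low in the buried core):

```python
from chaostopo.fixtures import synthetic_protein
from chaostopo.pipeline import predict_bfactors
from chaostopo.config import RunConfig

cloud, b = synthetic_protein(100, seed=1)
cfg = RunConfig(p=3, n_steps=2000, transient=500, seed=1)
X, fitted, pcc = predict_bfactors(cloud, b, cfg)
print(f"features: {X.values.shape[0]} residues x {X.values.shape[1]} columns")
print(f"in-sample PCC vs planted profile: {pcc:.3f}")
print(f"first three residues  planted {b[:3].round(1)}  fitted {fitted[:3].round(1)}")
```

prints

```
features: 100 residues x 63 columns
in-sample PCC vs planted profile: 0.999
first three residues  planted [10.   7.   5.4]  fitted [10.   6.8  5.4]
```

— 3 filtration scales × 3 components × 7 statistics give 63 features per
residue; the in-sample least-squares fit recovers the planted flexibility
profile almost exactly.  (The empty last filtration scale contributes
identical rows, so the design is rank-deficient and the fit warns and falls
back to the pseudoinverse — expected behavior.)

The synchronization transition that powers the features can be watched
directly from the command line:

```bash
chaostopo toy --geometry hexadecagon --scales 3
# -> none -> partial -> full
```

Sixteen Lorenz oscillators on a regular hexadecagon are uncoupled at a
small filtration radius (independent chaos), weakly coupled at an
intermediate radius (partial synchronization), and fully synchronized once
the radius spans the polygon.

Other CLI subcommands: `filtration` (emit the coupling-matrix family and
persistent-Laplacian spectra), `features`, `classify`, `bfactor` (from a
PDB file's Cα trace), and `fixtures` (write the synthetic data sets).

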