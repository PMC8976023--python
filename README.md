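# archcomp

Two-condition comparison of multiscale 3D genome architecture and
regulatory circuitry from Hi-C contact maps.

Pluripotent and differentiated cells organise their genomes differently:
pluripotent nuclei are dispersed — weak A/B compartmentalization, weak
topologically associating domains (TADs), little chromosome intermingling,
high contact-map entropy — while differentiated nuclei are compact and
ordered. `archcomp` quantifies that contrast between any two conditions at
every scale a binned contact map resolves, for computational biologists
working with Hi-C plus matched peak calls and replicate expression counts:

- **chromosome intermingling** — deterministic 3D reconstruction
  (distances `d = c^(-1/2)`, shortest-path completion, classical MDS) and
  the Shannon diversity `H = -Σ p_c ln p_c` of chromosome identities among
  each bead's k nearest neighbours; beads with `H ≥ ln 2` count as
  extensively intermingled;
- **contact-map disorder** — the Von Neumann entropy
  `VNE = -Σ λ ln λ` of the trace-normalized spectrum of each chromosome's
  O/E correlation matrix;
- **compartmentalization strength** — A/B calls from the leading
  eigenvector E1 of the O/E correlation matrix and the saddle statistic
  `AA·BB/AB²` over the extreme E1 quantiles;
- **TADs** — diamond insulation scores, boundary calls by prominence,
  boundary sharing between conditions, and the per-TAD
  `log2(intra/inter)` contact strength with strict distance matching;
- **compartment switch regions** — A-in-one/B-in-the-other runs, their
  size in Mb, and the expression shift of the genes inside them
  (median fold change, signed-rank test), plus permutation-tested peak
  enrichment;
- **regulatory circuitry** — promoter–enhancer interaction (PEI) calling
  from O/E contact, super-enhancer stitching (ROSE-style rank-curve
  elbow), the regulatory potential score
  `RPS(g) = Σ signal(e)·OE(p,e)`, RPS–expression covariation under BH FDR
  control, strict on/off expression filters, and promoter–promoter
  contact graphs stratified by expression.

A synthetic-data generator plants all of this structure (power-law decay,
checkerboard compartments, block TADs, loops, Poisson sampling, NB
expression with compartment-linked fold changes), so every stage is
verifiable against ground truth without any external download. Standard
formats (chrom.sizes, BED, bedGraph, COO text matrices, TSV tables) are
read and written directly.

## Worked example

```python
from archcomp import (
    stem_like_params, differentiated_like_params, simulate_architecture,
    simulate_contact_map, ice_balance, von_neumann_entropy,
    reconstruct_structure, intermingle_index,
)
from archcomp.pipeline import balance_and_oe
from archcomp.compartments import (
    compartment_eigenvector, compartment_strength, gene_density_track,
)

for name, preset in [("stem", stem_like_params), ("diff", differentiated_like_params)]:
    truth = simulate_architecture(preset(seed=1))
    m = simulate_contact_map(truth, 1, seed=5)     # 900 bins, depth 5e6
    oe, _ = balance_and_oe(m)                       # ICE + O/E
    track = compartment_eigenvector(oe, gene_density_track(truth.genes, truth.binning))
    strength = compartment_strength(oe, track).strength
    vne = von_neumann_entropy(oe).mean
    prob = intermingle_index(reconstruct_structure(m)).mean_probability
    print(f"{name}: strength={strength:.2f} VNE={vne:.2f} intermingle={prob:.3f}")
```

prints

```
stem: strength=1.85 VNE=5.01 intermingle=0.000
diff: strength=3.03 VNE=4.68 intermingle=0.042
```

The dispersed stem-like nucleus shows weaker compartmentalization (1.85 vs
3.03), higher contact-map entropy (5.01 vs 4.68), and essentially no
chromosome intermingling (0.000 vs 0.042) — the orderings expected between
a pluripotent and a differentiated genome. `archcomp.pipeline.
preset_comparison` runs the same contrast over replicate maps and adds
intra-TAD strength, boundary sharing, and PEI counts;
`condition_pair_analysis` covers switch regions, expression shifts, PEI
overlap, and RPS–expression covariation for the two planted conditions of
one architecture.

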