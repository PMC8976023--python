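"""End-to-end two-condition comparison on synthetic data.

Two entry points:

``preset_comparison`` contrasts a dispersed, stem-like architecture
(weak compartments, weak TADs, little trans contact, fewer loops) against a
compact, differentiated-like one across replicate Poisson-sampled maps and
reports the headline per-map statistics (intermingling probability, Von
Neumann entropy, compartment strength, intra-TAD strength, PEI counts,
boundary sharing) together with the qualitative orderings between the two
conditions.

``condition_pair_analysis`` analyses the two planted conditions of a single
architecture: compartment switch regions and their size, expression shifts
of switch-region genes, PEI overlap between conditions, and RPS-expression
covariation.

Both are deterministic given their base seed; every internal seed is derived
from it.
"""

from __future__ import annotations

import numpy as np

from .genome_model import GenomeBinning
from .synthetic import (
    ArchitectureTruth,
    SimParams,
    differentiated_like_params,
    simulate_architecture,
    simulate_contact_map,
    simulate_expression,
    simulate_peaks,
    stem_like_params,
)
from .contacts import ContactMatrix, expected_by_distance, ice_balance, observed_over_expected
from .compartments import (
    compartment_eigenvector,
    compartment_strength,
    gene_density_track,
    region_expression_shift,
    switch_regions,
)
from .domains import boundary_sharing, call_boundaries, insulation_score, intra_tad_strength
from .disorder3d import intermingle_index, reconstruct_structure, von_neumann_entropy
from .regulatory import (
    call_pei,
    define_enhancers,
    define_promoters,
    pei_overlap,
    regulatory_potential,
    rps_expression_covariation,
    strict_expression_filter,
)
from .stats_report import build_report, tpm, wilcoxon_rank_sum

__all__ = [
    "analyze_map",
    "preset_comparison",
    "condition_pair_analysis",
    "comparison_report",
    "tad_genome_params",
]

TAD_WINDOW_BP = 300_000
TAD_DELTA = 0.1


def tad_genome_params(base: SimParams, **overrides) -> SimParams:
    """Finer single-chromosome genome for TAD-scale analyses.

    1 x 10 Mb at 20-kb bins (500 bins); insulation windows and boundary
    calls need this resolution, while compartment/entropy/3D analyses use
    the coarser multi-chromosome default.
    """
    from dataclasses import replace

    # compartment runs stay at their physical ~1 Mb scale (50 bins at 20 kb)
    fields = dict(n_chroms=1, chrom_length=10_000_000, bin_size=20_000,
                  trans_level=0.0, trans_level2=0.0, n_loops=10, n_loops2=10,
                  comp_run_mean_bins=50.0)
    fields.update(overrides)
    return replace(base, **fields)


def balance_and_oe(m: ContactMatrix):
    """Convenience: ICE-balance a raw map and derive its O/E matrix."""
    ice_balance(m)
    profile = expected_by_distance(m)
    return observed_over_expected(m, profile), profile


def analyze_map(m: ContactMatrix, truth: ArchitectureTruth,
                with_structure: bool = True) -> dict:
    """Balance one map and compute its per-map architecture statistics."""
    oe, _ = balance_and_oe(m)
    density = gene_density_track(truth.genes, truth.binning)
    track = compartment_eigenvector(oe, density)
    saddle = compartment_strength(oe, track)
    vne = von_neumann_entropy(oe)
    out = {
        "vne": vne.mean,
        "compartment_strength": saddle.strength,
        "oe": oe,
        "track": track,
    }
    if with_structure and len(m.binning.chrom_names) >= 2:
        s3d = reconstruct_structure(m)
        prof = intermingle_index(s3d)
        out["intermingle_probability"] = prof.mean_probability
    return out


def _map_seed(base_seed: int, offset: int) -> int:
    return (base_seed * 10_007 + offset) % (2**31 - 1)


def preset_comparison(
    base_seed: int = 1,
    n_maps: int = 8,
    depth: float = 5e6,
    stem: SimParams | None = None,
    diff: SimParams | None = None,
) -> dict:
    """Full stem-like vs differentiated-like comparison on replicate maps.

    Draws ``n_maps`` Poisson replicate maps per preset from a shared genome
    layout (same TAD boundaries and gene placement, preset-specific contact
    structure), computes per-map VNE, intermingle probability, compartment
    strength and intra-TAD strength, calls PEIs per preset, and evaluates
    the six qualitative orderings expected between a dispersed and a
    compact nucleus.
    """
    stem = stem or stem_like_params(seed=base_seed, depth=depth)
    diff = diff or differentiated_like_params(seed=base_seed, depth=depth)
    truth_stem = simulate_architecture(stem)
    truth_diff = simulate_architecture(diff)

    metrics: dict[str, dict[str, list[float]]] = {
        "stem": {"vne": [], "intermingle_probability": [], "compartment_strength": []},
        "diff": {"vne": [], "intermingle_probability": [], "compartment_strength": []},
    }
    first_analysis: dict[str, dict] = {}
    for cond, truth in (("stem", truth_stem), ("diff", truth_diff)):
        for r in range(n_maps):
            offset = r + (0 if cond == "stem" else n_maps)
            seed = _map_seed(base_seed, 1 + offset)
            m = simulate_contact_map(truth, 1, seed=seed,
                                     name=f"{cond}-{r+1}", depth=depth)
            res = analyze_map(m, truth, with_structure=True)
            metrics[cond]["vne"].append(res["vne"])
            metrics[cond]["compartment_strength"].append(res["compartment_strength"])
            metrics[cond]["intermingle_probability"].append(
                res["intermingle_probability"])
            if r == 0:
                first_analysis[cond] = res

    # TAD-scale genome: intra-TAD strength per map and cross-preset sharing
    tstem = simulate_architecture(tad_genome_params(stem))
    tdiff = simulate_architecture(tad_genome_params(diff))
    tad_strength = {"stem": [], "diff": []}
    boundary_sets = {"stem": [], "diff": []}
    for cond, truth in (("stem", tstem), ("diff", tdiff)):
        for r in range(n_maps):
            offset = r + (0 if cond == "stem" else n_maps)
            seed = _map_seed(base_seed, 101 + offset)
            m = simulate_contact_map(truth, 1, seed=seed, depth=depth)
            ice_balance(m)
            prof = insulation_score(m, TAD_WINDOW_BP)
            tads = call_boundaries(prof, TAD_DELTA)
            boundary_sets[cond].append(tads)
            tad_strength[cond].append(intra_tad_strength(m, tads).mean)
    sharing = [
        boundary_sharing(a, b)["mean"]
        for a, b in zip(boundary_sets["stem"], boundary_sets["diff"])
    ]

    # PEI calling per preset on the first replicate map of each
    pei_counts = {}
    for cond, truth in (("stem", truth_stem), ("diff", truth_diff)):
        res = first_analysis[cond]
        seed = _map_seed(base_seed, 201 + (0 if cond == "stem" else 1))
        k27, _ = simulate_peaks(truth, 1, seed=seed)
        promoters = define_promoters(truth.genes, truth.binning)
        enhancers = define_enhancers(k27, promoters, truth.binning)
        m_first = simulate_contact_map(
            truth, 1, seed=_map_seed(base_seed, 1 + (0 if cond == "stem" else n_maps)),
            depth=depth)
        pei = call_pei(res["oe"], m_first, promoters, enhancers)
        pei_counts[cond] = len(pei)

    mean = {c: {k: float(np.mean(v)) for k, v in metrics[c].items()}
            for c in metrics}
    mean["stem"]["intra_tad_strength"] = float(np.mean(tad_strength["stem"]))
    mean["diff"]["intra_tad_strength"] = float(np.mean(tad_strength["diff"]))
    orderings = {
        "intermingle_lower_in_stem": mean["stem"]["intermingle_probability"]
        < mean["diff"]["intermingle_probability"],
        "vne_higher_in_stem": mean["stem"]["vne"] > mean["diff"]["vne"],
        "compartment_strength_lower_in_stem":
            mean["stem"]["compartment_strength"]
            < mean["diff"]["compartment_strength"],
        "intra_tad_strength_lower_in_stem":
            mean["stem"]["intra_tad_strength"] < mean["diff"]["intra_tad_strength"],
        "fewer_peis_in_stem": pei_counts["stem"] < pei_counts["diff"],
        "boundary_sharing_high": float(np.mean(sharing)) >= 0.9,
    }
    tests = {
        name: wilcoxon_rank_sum(metrics["stem"][name], metrics["diff"][name]).p
        for name in ("vne", "compartment_strength", "intermingle_probability")
    }
    tests["intra_tad_strength"] = wilcoxon_rank_sum(
        tad_strength["stem"], tad_strength["diff"]).p
    return {
        "per_map": {c: {k: v for k, v in metrics[c].items()} for c in metrics},
        "tad_strength": tad_strength,
        "boundary_sharing": float(np.mean(sharing)),
        "pei_counts": pei_counts,
        "mean": mean,
        "orderings": orderings,
        "all_orderings_hold": all(orderings.values()),
        "tests": tests,
    }


def comparison_report(pc: dict, cp: dict, base_seed: int,
                      conditions=("stem_like", "differentiated_like")):
    """Assemble the schema-versioned report from the two pipeline outputs.

    ``pc`` is a :func:`preset_comparison` result and ``cp`` a
    :func:`condition_pair_analysis` result; serialization is deterministic.
    """
    metrics = {
        "per_condition": pc["mean"],
        "boundary_sharing": pc["boundary_sharing"],
        "pei_counts": pc["pei_counts"],
        "orderings": {k: bool(v) for k, v in pc["orderings"].items()},
        "switch_regions": cp["switch_regions"],
        "expression_shift": {
            k: {kk: vv for kk, vv in v.items()}
            for k, v in cp["expression_shift"].items()
        },
        "pei_overlap": cp["pei"],
        "covariation_gene_count": cp["covariation_gene_count"],
        "strict_filter_gene_count": cp["strict_filter_gene_count"],
    }
    tests = dict(pc["tests"])
    config = {
        "depth": 5e6,
        "tad_window_bp": TAD_WINDOW_BP,
        "tad_delta": TAD_DELTA,
    }
    return build_report(metrics, tests, config, {"base_seed": base_seed},
                        conditions=conditions)


def condition_pair_analysis(
    base_seed: int = 1,
    params: SimParams | None = None,
    expression_genes: int = 20_000,
) -> dict:
    """Within-architecture comparison of the two planted conditions.

    Covers compartment switch regions (size in Mb, gene counts, median fold
    changes with signed-rank p-values), PEI overlap between the conditions,
    RPS-expression covariation, and the strict high/low expression filter.
    A denser gene complement (``expression_genes``) is used for the
    expression-shift statistics so switch regions carry enough genes for a
    stable median.
    """
    from dataclasses import replace

    params = params or SimParams(seed=base_seed)
    truth = simulate_architecture(params)

    maps = {}
    analyses = {}
    for cond in (1, 2):
        m = simulate_contact_map(truth, cond, seed=_map_seed(base_seed, 300 + cond))
        maps[cond] = m
        analyses[cond] = analyze_map(m, truth, with_structure=False)

    regions = switch_regions(analyses[1]["track"], analyses[2]["track"])

    # expression shift over a denser gene set on the same architecture
    dense_truth = simulate_architecture(replace(params, n_genes=expression_genes))
    counts1 = simulate_expression(dense_truth, 1, seed=_map_seed(base_seed, 310))
    counts2 = simulate_expression(dense_truth, 2, seed=_map_seed(base_seed, 311))
    lengths = {g.gene_id: g.length for g in dense_truth.genes}
    import pandas as pd

    lens = pd.Series(lengths)
    tpm1 = tpm(counts1, lens)
    tpm2 = tpm(counts2, lens)
    shift = {}
    for name, ivs in (("restricted_a", regions.restricted_a),
                      ("restricted_b", regions.restricted_b)):
        try:
            n, med, test = region_expression_shift(
                ivs, dense_truth.genes, tpm1.mean(axis=1).to_numpy(),
                tpm2.mean(axis=1).to_numpy())
            shift[name] = {"n_genes": n, "median_fc": med, "p": test.p}
        except ValueError:
            shift[name] = {"n_genes": 0, "median_fc": float("nan"), "p": float("nan")}

    # PEI overlap and RPS covariation on the standard gene complement
    peis = {}
    rps = {}
    enh_sets = {}
    for cond in (1, 2):
        k27, _ = simulate_peaks(truth, cond, seed=_map_seed(base_seed, 320 + cond))
        promoters = define_promoters(truth.genes, truth.binning)
        enhancers = define_enhancers(k27, promoters, truth.binning)
        enh_sets[cond] = enhancers
        peis[cond] = call_pei(analyses[cond]["oe"], maps[cond], promoters,
                              enhancers, condition=str(cond))
        all_gene_ids = [g.gene_id for g in truth.genes]
        rps[cond] = regulatory_potential(peis[cond], enhancers, all_gene_ids)
    shared, pct1, pct2 = pei_overlap(peis[1], peis[2])

    ecounts1 = simulate_expression(truth, 1, seed=_map_seed(base_seed, 330))
    ecounts2 = simulate_expression(truth, 2, seed=_map_seed(base_seed, 331))
    glens = pd.Series({g.gene_id: g.length for g in truth.genes})
    cov_genes, _ = rps_expression_covariation(
        rps[1], rps[2], ecounts1, ecounts2, glens)
    et1 = tpm(ecounts1, glens)
    et2 = tpm(ecounts2, glens)
    strict = strict_expression_filter(et1, et2)

    return {
        "switch_regions": {
            "restricted_a_mb": regions.restricted_a_mb,
            "restricted_b_mb": regions.restricted_b_mb,
        },
        "expression_shift": shift,
        "pei": {"n_condition1": len(peis[1]), "n_condition2": len(peis[2]),
                "shared": shared, "pct_of_1": pct1, "pct_of_2": pct2},
        "covariation_gene_count": len(cov_genes),
        "strict_filter_gene_count": len(strict),
        "regions": regions,
        "truth": truth,
    }
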