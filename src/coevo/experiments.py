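"""End-to-end experiment drivers over the synthetic families.

These functions wire the pipeline stages together at fixed, desk-scale
problem sizes and return the quantities the analysis scripts and the test
suite report: null-calibration mode counts, planted-sector recovery
Jaccard indices before and after refinement, and the planted
selectivity-cell rank and pattern classification with its label-shuffled
negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import patterns as pat
from .alignment import compute_sequence_weights, position_set_overlap
from .integrated import build_concatenated_alignment, cross_sector_coupling
from .refine import RefinementParams, refine_sectors
from .sca import (assign_conservation_classes, coupling_matrix,
                  estimate_frequencies, extract_sectors, noise_clean,
                  positional_conservation)
from .simulate import SyntheticSpec, generate_families, generate_null_alignment


def jaccard(a, b) -> float:
    """Jaccard index between two position-label collections."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class ScaResult:
    weights: object
    freqs: object
    profile: object
    C: object
    spectral: object
    sectors: list


def run_sca(aln, identity_threshold=0.8, lambda_pc=0.03, n_rand=10,
            rand_quantile=1.0, ic_quantile=0.95, min_size=5,
            seed=None) -> ScaResult:
    """Weights → frequencies → conservation → coupling → noise cleaning →
    sectors, with conservation classes assigned."""
    weights = compute_sequence_weights(aln, identity_threshold)
    freqs = estimate_frequencies(aln, weights, lambda_pc=lambda_pc)
    profile = positional_conservation(freqs)
    C = coupling_matrix(aln, weights, freqs)
    spectral = noise_clean(C, aln, weights, n_rand=n_rand,
                           rand_quantile=rand_quantile, seed=seed,
                           lambda_pc=lambda_pc)
    sectors = extract_sectors(spectral, C, ic_quantile=ic_quantile,
                              min_size=min_size)
    assign_conservation_classes(profile, sectors)
    return ScaResult(weights, freqs, profile, C, spectral, sectors)


def null_calibration(n_seeds=20, n_seq=200, n_pos=50, n_rand=20,
                     seed=0) -> list:
    """k_star of the noise-cleaning step on i.i.d. background alignments.

    With no planted structure the real spectrum should rarely exceed the
    column-permutation maxima; returns the list of k_star values.
    """
    out = []
    for k in range(n_seeds):
        aln = generate_null_alignment(n_seq, n_pos, seed=seed * 10_000 + k)
        weights = compute_sequence_weights(aln)
        freqs = estimate_frequencies(aln, weights)
        C = coupling_matrix(aln, weights, freqs)
        spectral = noise_clean(C, aln, weights, n_rand=n_rand,
                               seed=seed * 10_000 + k + 1)
        out.append(spectral.k_star)
    return out


def best_sector_jaccard(sectors, planted) -> float:
    """Best Jaccard of any extracted sector against a planted position set."""
    if not sectors:
        return 0.0
    return max(jaccard(s.positions, planted) for s in sectors)


def sector_recovery(seed=0, n_rand=10, refine_params=None,
                    spec_overrides=None) -> dict:
    """One planted-sector recovery run on the default synthetic family.

    Returns the Jaccard of the best-matching extracted sector against the
    planted coevolved receptor sector, before and after refinement.
    """
    spec = SyntheticSpec(seed=seed)
    if spec_overrides:
        spec = replace(spec, **spec_overrides)
    receptor_aln, _, _, truth = generate_families(spec)
    res = run_sca(receptor_aln, n_rand=n_rand, seed=seed + 1)
    planted = truth.receptor_sectors["coevolved"]
    j_raw = best_sector_jaccard(res.sectors, planted)
    refined, _ = refine_sectors(res.C, res.sectors,
                                refine_params or RefinementParams(),
                                spectral=res.spectral)
    j_ref = best_sector_jaccard(refined, planted)
    return {"seed": seed, "jaccard_raw": j_raw, "jaccard_refined": j_ref,
            "k_star": res.spectral.k_star, "n_sectors": len(res.sectors),
            "result": res, "refined": refined, "truth": truth}


def sector_recovery_sweep(n_seeds=20, n_rand=10, base_seed=0) -> pd.DataFrame:
    rows = []
    for k in range(n_seeds):
        r = sector_recovery(seed=base_seed + k, n_rand=n_rand)
        rows.append({k2: r[k2] for k2 in
                     ("seed", "jaccard_raw", "jaccard_refined", "k_star",
                      "n_sectors")})
    return pd.DataFrame(rows)


def _shuffle_family_labels(galpha_aln, rng):
    """Negative control: permute family annotations across G-alpha rows."""
    shuffled = galpha_aln.seq_meta.copy()
    fams = shuffled["protein_family"].to_numpy().copy()
    rng.shuffle(fams)
    shuffled["protein_family"] = fams
    out = galpha_aln.subset()
    out.seq_meta = shuffled
    return out


def selectivity_recovery(seed=0, shuffle_labels=False,
                         spec_overrides=None) -> dict:
    """Cross-sector coupling + pattern classification on planted selectivity.

    Builds the concatenated alignment over the planted receptor and
    G-alpha sector positions (coevolved + selectivity + conserved), computes
    the cross block, and scores the planted (receptor, G-alpha) selectivity
    cell: its percentile within the block and its pattern partition.  With
    ``shuffle_labels=True`` the G-alpha family annotations are permuted
    first, destroying the coupling-dependent signal.
    """
    spec = SyntheticSpec(seed=seed)
    if spec_overrides:
        spec = replace(spec, **spec_overrides)
    receptor_aln, galpha_aln, coupling, truth = generate_families(spec)
    rng = np.random.default_rng(seed + 7)
    if shuffle_labels:
        galpha_aln = _shuffle_family_labels(galpha_aln, rng)

    r_positions = (truth.receptor_sectors["coevolved"]
                   + truth.receptor_sectors["selectivity"]
                   + truth.receptor_sectors["conserved"])
    g_positions = (truth.galpha_sectors["coevolved"]
                   + truth.galpha_sectors["selectivity"]
                   + truth.galpha_sectors["conserved"])
    concat = build_concatenated_alignment(receptor_aln, galpha_aln, coupling,
                                          r_positions, g_positions)
    weights = compute_sequence_weights(concat.aln)
    _, block = cross_sector_coupling(concat, weights)

    r_star = truth.receptor_sectors["selectivity"][0]
    g_star = truth.galpha_sectors["selectivity"][0]
    cell_value = float(block.loc[r_star, g_star])
    flat = block.to_numpy().ravel()
    percentile = float((flat <= cell_value).mean() * 100)

    cell = pat.make_pattern_cell(concat, r_star, g_star)
    planted_partition = pat.canonical_partition(truth.selectivity_grouping)
    return {
        "seed": seed,
        "block": block,
        "concat": concat,
        "truth": truth,
        "cell_value": cell_value,
        "percentile": percentile,
        "median_block": float(np.median(flat)),
        "partition": cell.partition,
        "partition_code": cell.partition_code,
        "planted_partition": planted_partition,
        "partition_match": cell.partition == planted_partition,
    }


def overlap_summary(sectors_a, sectors_b) -> pd.DataFrame:
    """Pairwise Venn-style overlaps between two lists of sectors."""
    rows = []
    for sa in sectors_a:
        for sb in sectors_b:
            rep = position_set_overlap(sa.positions, sb.positions)
            rows.append({"sector_a": sa.name, "sector_b": sb.name,
                         "shared": rep.shared,
                         "a_only": rep.set_a_only, "b_only": rep.set_b_only,
                         "fraction_of_a": rep.fraction_of_a,
                         "fraction_of_b": rep.fraction_of_b})
    return pd.DataFrame(rows)
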