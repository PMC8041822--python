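"""Sector refinement by noise-corrected coupling similarity.

Eigenvector-based sector extraction can miss strongly coupled positions or
keep weakly coupled ones.  Refinement scores every position by its mean
similarity to a sector's members, standardizes that score against the
non-member distribution, then admits pronounced outsiders (z >= z_add) and
drops weak members (z < z_drop), iterating to a fixed point.

The pairwise similarity is, by preference, the *noise-corrected* coupling
(C - mean_rand) / sd_rand, standardized element-wise against the
column-permutation null recorded during noise cleaning: conservation
inflates every coupling a highly conserved position participates in
(through the phi weights), and the permutation null carries exactly that
inflation, so standardizing removes it.  When no null is available the
conservation-normalized coupling C[i][j]/sqrt(C[i][i] C[j][j]) is used
instead.

The default z_add of 4 is deliberately strict: with of order 10^2
candidate positions, a 2-sigma cut admits the top of the background tail
on every call, whereas a 4-sigma score is a genuinely pronounced
similarity.  A position dropped from a sector is never re-admitted to it,
which together with z_add >= z_drop rules out oscillation.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sca import CouplingMatrix, Sector, SpectralModel


@dataclass
class RefinementParams:
    z_add: float = 4.0
    z_drop: float = 1.5
    max_iter: int = 10

    def __post_init__(self):
        if self.z_add < self.z_drop:
            raise ValueError("z_add must be >= z_drop to prevent oscillation")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def normalized_coupling(C: CouplingMatrix) -> np.ndarray:
    """N[i][j] = C[i][j] / sqrt(C[i][i] C[j][j]) with unit diagonal."""
    d = np.sqrt(np.clip(np.diag(C.values), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        N = C.values / np.outer(d, d)
    N[~np.isfinite(N)] = 0.0
    np.fill_diagonal(N, 1.0)
    return N


def similarity_matrix(C: CouplingMatrix,
                      spectral: SpectralModel | None = None) -> np.ndarray:
    """Pairwise similarity used by refinement.

    With a noise-cleaning null available: element-wise z of C against the
    column-permutation ensemble.  Without: conservation-normalized
    coupling.
    """
    if spectral is not None and spectral.rand_mean is not None:
        sd = np.where(spectral.rand_sd > 0, spectral.rand_sd,
                      np.nanmax(spectral.rand_sd) or 1.0)
        S = (C.values - spectral.rand_mean) / sd
        np.fill_diagonal(S, 0.0)
        return S
    return normalized_coupling(C)


def sector_similarity_profile(C: CouplingMatrix, sector: Sector,
                              spectral: SpectralModel | None = None
                              ) -> pd.Series:
    """Z-scored mean similarity of every position to the sector's members.

    The raw score of position p is the mean of S[p][m] over members m != p
    (S the similarity matrix); z-scores are taken against the distribution
    of raw scores over non-member positions, with robust location/scale
    (median and Gaussian-consistent MAD) so that strongly coupled
    positions the extraction missed do not inflate their own reference.
    Singleton sectors have no defined similarity.
    """
    if len(sector.positions) < 2:
        raise ValueError(
            f"sector '{sector.name}' has a single position; similarity undefined"
        )
    pos_index = {p: i for i, p in enumerate(C.positions)}
    missing = [p for p in sector.positions if p not in pos_index]
    if missing:
        raise KeyError(f"sector positions not in coupling matrix: {missing}")
    S = similarity_matrix(C, spectral)
    members = np.array([pos_index[p] for p in sector.positions])
    member_mask = np.zeros(len(C.positions), dtype=bool)
    member_mask[members] = True

    sums = S[:, members].sum(axis=1)
    counts = np.full(len(C.positions), len(members), dtype=float)
    # members exclude their own (diagonal) contribution
    sums[members] -= S[members, members]
    counts[members] -= 1
    raw = sums / counts

    outside = raw[~member_mask]
    mu = float(np.median(outside)) if outside.size else 0.0
    sd = 1.4826 * float(np.median(np.abs(outside - mu))) if outside.size else 1.0
    if sd == 0:
        sd = float(outside.std()) or 1.0
    return pd.Series((raw - mu) / sd, index=C.positions, name=sector.name)


def refine_sectors(C: CouplingMatrix, sectors: list,
                   params: RefinementParams | None = None,
                   spectral: SpectralModel | None = None):
    """Admit strong outsiders and drop weak members until nothing changes.

    Within each iteration admissions happen before removals; a position
    admitted to several sectors' candidate lists goes to the sector where
    its z-score is largest.  A position dropped from a sector is never
    re-admitted to it.  Disjointness is preserved throughout.

    Returns
    -------
    (list of Sector, dict)
        Refined sectors and a change log with per-iteration admissions and
        drops plus a ``converged`` flag.
    """
    params = params or RefinementParams()
    seen = set()
    for sec in sectors:
        dup = seen & set(sec.positions)
        if dup:
            raise ValueError(f"input sectors are not disjoint: {sorted(dup)}")
        seen |= set(sec.positions)

    current = copy.deepcopy(sectors)
    banned = {s.name: set() for s in current}  # dropped → no re-admission
    log = {"iterations": [], "converged": True}
    for _ in range(params.max_iter):
        added, dropped = [], []
        assigned = set().union(*(set(s.positions) for s in current)) if current else set()

        profiles = {s.name: sector_similarity_profile(C, s, spectral)
                    for s in current if len(s.positions) >= 2}
        # admissions: unassigned positions with z >= z_add join their best sector
        candidates = {}
        for name, z in profiles.items():
            for p in C.positions:
                if p in assigned or p in banned[name]:
                    continue
                if z[p] >= params.z_add:
                    best_name, best_z = candidates.get(p, (None, -np.inf))
                    if z[p] > best_z:
                        candidates[p] = (name, float(z[p]))
        by_name = {s.name: s for s in current}
        for p, (name, zval) in candidates.items():
            sec = by_name[name]
            sec.positions.append(p)
            sec.loadings[p] = zval
            assigned.add(p)
            added.append((p, name, zval))

        # drops: members below z_drop leave (profiles recomputed after adds)
        for sec in current:
            if len(sec.positions) < 3:
                continue
            z = sector_similarity_profile(C, sec, spectral)
            weak = [p for p in sec.positions if z[p] < params.z_drop]
            if len(weak) >= len(sec.positions) - 1:
                continue  # refuse to dissolve the sector
            for p in weak:
                sec.positions.remove(p)
                sec.loadings.pop(p, None)
                assigned.discard(p)
                banned[sec.name].add(p)
                dropped.append((p, sec.name, float(z[p])))

        current = [s for s in current if s.positions]
        log["iterations"].append({"added": added, "dropped": dropped})
        if not added and not dropped:
            break
    else:
        warnings.warn("sector refinement did not converge within max_iter")
        log["converged"] = False
    return current, log
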