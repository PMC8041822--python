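"""Statistical coupling analysis: conservation, coupling matrix, sectors.

The method quantifies, for a multiple sequence alignment, (i) how conserved
each position is — the Kullback–Leibler divergence (KLD, in nats) of its
amino-acid frequencies from a background distribution — and (ii) how much
pairs of positions co-evolve — a conservation-weighted covariance between
positions collapsed into a positional coupling matrix C.  Statistical noise
is removed by comparing the spectrum of C to spectra obtained from
column-permuted alignments (which keep composition but destroy
correlations); the surviving eigenmodes are rotated into independent
components, and heavy-tailed outlier positions on each component form
*sectors* — groups of jointly conserved or coevolving positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import ALPHABET, N_SYMBOLS, LabeledAlignment, SequenceWeights

# Standard database amino-acid frequencies (order ARNDCQEGHILKMFPSTWYV),
# as used by the reference SCA toolboxes.
_RESIDUE_BACKGROUND = {
    "A": 0.073, "R": 0.052, "N": 0.043, "D": 0.050, "C": 0.025,
    "Q": 0.040, "E": 0.061, "G": 0.072, "H": 0.023, "I": 0.053,
    "L": 0.089, "K": 0.064, "M": 0.023, "F": 0.042, "P": 0.052,
    "S": 0.073, "T": 0.056, "W": 0.013, "Y": 0.033, "V": 0.063,
}

#: significance-star convention used in sector conservation comparisons
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def background_frequencies(gap_background: float = 0.05) -> np.ndarray:
    """Background distribution over the 21-symbol alphabet.

    The gap symbol gets ``gap_background`` mass; residue frequencies are
    renormalized over the remainder.
    """
    if not 0 < gap_background < 1:
        raise ValueError("gap_background must lie in (0, 1)")
    q = np.empty(N_SYMBOLS)
    res = np.array([_RESIDUE_BACKGROUND[c] for c in ALPHABET[:-1]])
    q[:-1] = res / res.sum() * (1.0 - gap_background)
    q[-1] = gap_background
    if np.any(q <= 0):
        raise ValueError("background frequencies must be strictly positive")
    return q


def _one_hot(idx: np.ndarray) -> np.ndarray:
    n_seq, n_pos = idx.shape
    X = np.zeros((n_seq, n_pos, N_SYMBOLS))
    rows = np.repeat(np.arange(n_seq), n_pos)
    cols = np.tile(np.arange(n_pos), n_seq)
    X[rows, cols, idx.ravel()] = 1.0
    return X


@dataclass
class FrequencyModel:
    """Regularized single and pairwise amino-acid frequencies.

    ``f1[i, a]`` mixes the weighted empirical frequency with the background
    ``q`` using pseudocount weight ``lambda_pc``; ``f2`` does the same with
    the product background on off-diagonal position pairs.  Diagonal blocks
    are ``diag(f1[i])`` exactly (a column paired with itself).
    """

    f1: np.ndarray                 # (n_pos, 21)
    f2_flat: np.ndarray            # (n_pos*21, n_pos*21)
    q: np.ndarray                  # (21,)
    lambda_pc: float
    positions: list

    @property
    def n_pos(self) -> int:
        return self.f1.shape[0]

    def f2(self, i: int, j: int) -> np.ndarray:
        """Pairwise frequency block (21, 21) for positions i, j."""
        s = N_SYMBOLS
        return self.f2_flat[i * s:(i + 1) * s, j * s:(j + 1) * s]


@dataclass
class ConservationProfile:
    """Positional conservation derived from a FrequencyModel.

    ``D[i]`` is the 21-letter relative entropy of position i from the
    background (nats); ``D_binary[i, a]`` the residue-binarized form;
    ``phi[i, a]`` the conservation-gradient weights used to build the
    coupling matrix.
    """

    D: np.ndarray            # (n_pos,)
    D_binary: np.ndarray     # (n_pos, 21)
    phi: np.ndarray          # (n_pos, 21)
    positions: list
    q: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.D, index=self.positions, name="KLD")


@dataclass
class CouplingMatrix:
    """Symmetric non-negative positional coevolution matrix."""

    values: np.ndarray
    positions: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("coupling matrix must be square")
        if len(self.positions) != self.values.shape[0]:
            raise ValueError("positions length must match matrix size")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.positions,
                            columns=self.positions)


@dataclass
class SpectralModel:
    """Noise-cleaned spectral decomposition of a coupling matrix.

    ``rand_mean``/``rand_sd`` hold the element-wise mean and standard
    deviation of the coupling matrix over the column-permutation trials —
    the per-pair noise null that downstream refinement standardizes
    against.
    """

    eigenvalues: np.ndarray            # descending
    eigenvectors: np.ndarray           # (n_pos, n_pos), column k ↔ eigenvalue k
    W: np.ndarray                      # (n_pos, k_star) independent components
    k_star: int
    random_spectrum_quantile: float    # the eigenvalue cutoff used
    positions: list
    rand_mean: np.ndarray | None = None
    rand_sd: np.ndarray | None = None


@dataclass
class Sector:
    """A named group of positions with loadings and a conservation class."""

    name: str
    positions: list
    loadings: dict
    conservation_class: str = "unassigned"

    def __post_init__(self):
        if not self.positions:
            raise ValueError("sector must contain at least one position")


def estimate_frequencies(aln: LabeledAlignment, weights: SequenceWeights,
                         lambda_pc: float = 0.03,
                         q: np.ndarray | None = None) -> FrequencyModel:
    """Weighted, pseudocount-regularized frequency estimation.

    f1[i][a] = (1-λ)·(Σ_s w_s [x_si = a])/M_eff + λ·q[a]; pairwise f2
    analogously with the product background q[a]q[b] on distinct position
    pairs.  Normalizations hold to machine precision.
    """
    if lambda_pc >= 1 or lambda_pc < 0:
        raise ValueError("lambda_pc must lie in [0, 1)")
    q = background_frequencies() if q is None else np.asarray(q, dtype=float)
    idx = aln.to_indices()
    w = weights.w_s
    if len(w) != aln.n_seq:
        raise ValueError("weights do not match alignment")
    X = _one_hot(idx)
    Xf = X.reshape(aln.n_seq, -1)
    f1_raw = (w[:, None] * Xf).sum(axis=0) / weights.M_eff
    f2_raw = (w[:, None] * Xf).T @ Xf / weights.M_eff
    f1 = (1 - lambda_pc) * f1_raw.reshape(aln.n_pos, N_SYMBOLS) \
        + lambda_pc * q[None, :]
    qq = np.outer(q, q)
    f2 = (1 - lambda_pc) * f2_raw + lambda_pc * np.tile(qq, (aln.n_pos, aln.n_pos))
    s = N_SYMBOLS
    for i in range(aln.n_pos):
        f2[i * s:(i + 1) * s, i * s:(i + 1) * s] = np.diag(f1[i])
    return FrequencyModel(f1=f1, f2_flat=f2, q=q, lambda_pc=lambda_pc,
                          positions=list(aln.position_labels))


def positional_conservation(freqs: FrequencyModel) -> ConservationProfile:
    """KLD conservation profile and conservation-gradient weights.

    D[i] = Σ_a f1[i][a] ln(f1[i][a]/q[a]) with 0·ln 0 = 0.  The binarized
    form treats each residue as present/absent.  φ[i][a] = ln[f(1-q)/((1-f)q)]
    with f floored at λ·q and capped at 1-λ·(1-q) to keep logs finite.
    """
    f1, q = freqs.f1, freqs.q
    if np.any(q <= 0):
        raise ValueError("background contains zeros")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f1 > 0, f1 * np.log(f1 / q[None, :]), 0.0)
    D = terms.sum(axis=1)
    lam = max(freqs.lambda_pc, 1e-6)
    f = np.clip(f1, lam * q[None, :], 1.0 - lam * (1.0 - q[None, :]))
    D_binary = f * np.log(f / q) + (1 - f) * np.log((1 - f) / (1 - q))
    phi = np.log(f * (1 - q[None, :]) / ((1 - f) * q[None, :]))
    return ConservationProfile(D=D, D_binary=D_binary, phi=phi,
                               positions=list(freqs.positions), q=q)


def _coupling_values(f1_flat: np.ndarray, f2_flat: np.ndarray,
                     phi_flat: np.ndarray, n_pos: int) -> np.ndarray:
    """C[i][j] = ||phi_i^a phi_j^b (f2 - f1 f1)||_F over residue pairs."""
    T = phi_flat[:, None] * (f2_flat - np.outer(f1_flat, f1_flat)) * phi_flat[None, :]
    T2 = (T ** 2).reshape(n_pos, N_SYMBOLS, n_pos, N_SYMBOLS)
    C = np.sqrt(T2.sum(axis=(1, 3)))
    return 0.5 * (C + C.T)  # symmetrize away rounding asymmetry


def coupling_matrix(aln: LabeledAlignment, weights: SequenceWeights,
                    freqs: FrequencyModel) -> CouplingMatrix:
    """Positional coupling matrix from conservation-weighted covariance."""
    profile = positional_conservation(freqs)
    C = _coupling_values(freqs.f1.ravel(), freqs.f2_flat,
                         profile.phi.ravel(), freqs.n_pos)
    return CouplingMatrix(values=C, positions=list(freqs.positions))


def _coupling_from_indices(idx: np.ndarray, w: np.ndarray, M_eff: float,
                           lambda_pc: float, q: np.ndarray) -> np.ndarray:
    """Fast path: coupling values straight from an integer matrix."""
    n_seq, n_pos = idx.shape
    X = _one_hot(idx).reshape(n_seq, -1)
    f1_raw = (w[:, None] * X).sum(axis=0) / M_eff
    f2 = (w[:, None] * X).T @ X / M_eff
    f1 = (1 - lambda_pc) * f1_raw.reshape(n_pos, N_SYMBOLS) + lambda_pc * q[None, :]
    f2 *= (1 - lambda_pc)
    f2 += lambda_pc * np.tile(np.outer(q, q), (n_pos, n_pos))
    s = N_SYMBOLS
    for i in range(n_pos):
        f2[i * s:(i + 1) * s, i * s:(i + 1) * s] = np.diag(f1[i])
    lam = max(lambda_pc, 1e-6)
    f = np.clip(f1, lam * q[None, :], 1.0 - lam * (1.0 - q[None, :]))
    phi = np.log(f * (1 - q[None, :]) / ((1 - f) * q[None, :]))
    return _coupling_values(f1.ravel(), f2, phi.ravel(), n_pos)


def _rotate_ica(U_top: np.ndarray, seed: int | None) -> np.ndarray:
    """Rotate retained eigenvectors into independent components.

    Column signs are fixed so each component's largest-magnitude loading is
    positive; a single mode is returned as-is.
    """
    k = U_top.shape[1]
    if k <= 1:
        W = U_top.copy()
    else:
        from sklearn.decomposition import FastICA
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=k, whiten="unit-variance",
                          max_iter=1000, tol=1e-4,
                          random_state=None if seed is None else seed % (2**31))
            W = ica.fit_transform(U_top)
    for col in range(W.shape[1]):
        peak = np.argmax(np.abs(W[:, col]))
        if W[peak, col] < 0:
            W[:, col] = -W[:, col]
    return W


def noise_clean(C: CouplingMatrix, aln: LabeledAlignment,
                weights: SequenceWeights, n_rand: int = 100,
                rand_quantile: float = 1.0, seed: int | None = None,
                lambda_pc: float = 0.03,
                q: np.ndarray | None = None) -> SpectralModel:
    """Separate signal eigenmodes from alignment-composition noise.

    Each randomization trial permutes every alignment column independently,
    which preserves per-column composition but destroys inter-column
    correlation; the coupling matrix of the permuted alignment is
    recomputed and its largest eigenvalue recorded.  Eigenvalues of the
    real matrix above the ``rand_quantile`` quantile of those maxima count
    as significant (``k_star``), and the corresponding eigenvectors are
    rotated into independent components.
    """
    if n_rand < 10:
        raise ValueError("n_rand must be at least 10")
    q = background_frequencies() if q is None else np.asarray(q, dtype=float)
    evals, evecs = np.linalg.eigh(C.values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    rng = np.random.default_rng(seed)
    idx = aln.to_indices()
    maxima = np.empty(n_rand)
    acc = np.zeros_like(C.values)
    acc2 = np.zeros_like(C.values)
    for t in range(n_rand):
        permuted = rng.permuted(idx, axis=0)  # independent shuffle per column
        Cr = _coupling_from_indices(permuted, weights.w_s, weights.M_eff,
                                    lambda_pc, q)
        maxima[t] = np.linalg.eigvalsh(Cr)[-1]
        acc += Cr
        acc2 += Cr ** 2
    cutoff = float(np.quantile(maxima, rand_quantile))
    rand_mean = acc / n_rand
    rand_sd = np.sqrt(np.clip(acc2 / n_rand - rand_mean ** 2, 0, None))
    k_star = int(np.sum(evals > cutoff))
    W = _rotate_ica(evecs[:, :k_star], seed) if k_star else np.zeros((len(evals), 0))
    return SpectralModel(eigenvalues=evals, eigenvectors=evecs, W=W,
                         k_star=k_star, random_spectrum_quantile=cutoff,
                         positions=list(C.positions),
                         rand_mean=rand_mean, rand_sd=rand_sd)


def _tail_threshold(w: np.ndarray, ic_quantile: float) -> float:
    """Upper-tail cutoff from a robustly fitted location-scale t null.

    A straight t fit is distorted when a sizable fraction of the loadings
    are signal, so location and scale come from the median and the
    (Gaussian-consistent) MAD, and the tail index is fitted only on the
    inlier bulk (|z| <= 3).
    """
    loc = float(np.median(w))
    scale = 1.4826 * float(np.median(np.abs(w - loc)))
    if scale <= 0:
        scale = float(np.std(w)) or 1.0
    inliers = w[np.abs(w - loc) <= 3 * scale]
    df = 5.0
    if inliers.size >= 8 and np.ptp(inliers) > 0:
        try:
            df, _, _ = stats.t.fit(inliers, floc=loc, fscale=scale)
        except Exception:  # degenerate bulk: keep the moderate-tail default
            pass
    return float(loc + scale * stats.t.ppf(ic_quantile, max(df, 1.0)))


def extract_sectors(spectral: SpectralModel, C: CouplingMatrix,
                    ic_quantile: float = 0.95, min_size: int = 5) -> list:
    """Heavy-tailed outlier positions on each retained component.

    A location-scale t distribution is fitted to each component's loadings;
    positions beyond its ``ic_quantile`` upper tail (after flipping the
    component so its dominant loading is positive) qualify.  A position
    qualifying on several components joins the one where its loading
    magnitude is largest (ties: lower component index); sectors smaller
    than ``min_size`` are dropped.
    """
    if spectral.k_star == 0 or spectral.W.shape[1] == 0:
        return []
    n_pos, k = spectral.W.shape
    qualifies = np.zeros((n_pos, k), dtype=bool)
    for comp in range(k):
        w = spectral.W[:, comp]
        thr = _tail_threshold(w, ic_quantile)
        qualifies[:, comp] = w >= thr
    assignment = np.full(n_pos, -1)
    for p in range(n_pos):
        comps = np.nonzero(qualifies[p])[0]
        if comps.size:
            mags = np.abs(spectral.W[p, comps])
            assignment[p] = comps[np.argmax(mags)]  # argmax takes lowest index on ties
    sectors = []
    for comp in range(k):
        members = np.nonzero(assignment == comp)[0]
        if members.size < min_size:
            continue
        labels = [spectral.positions[p] for p in members]
        loadings = {spectral.positions[p]: float(spectral.W[p, comp])
                    for p in members}
        sectors.append(Sector(name=f"sector_{len(sectors) + 1}",
                              positions=labels, loadings=loadings))
    return sectors


def compare_sector_conservation(profile: ConservationProfile,
                                sectors: list) -> pd.DataFrame:
    """Pairwise Mann–Whitney U tests on sector KLD distributions.

    Returns one row per sector pair with U, the two-sided p-value, the two
    medians and a significance-star rendering (**** for p <= 1e-4).
    Sectors with fewer than two positions are skipped with a warning.
    """
    pos_index = {p: i for i, p in enumerate(profile.positions)}
    usable = []
    for sec in sectors:
        if len(sec.positions) < 2:
            warnings.warn(f"sector '{sec.name}' has < 2 positions; skipped")
            continue
        usable.append((sec.name, np.array([profile.D[pos_index[p]]
                                           for p in sec.positions])))
    rows = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            name_a, d_a = usable[a]
            name_b, d_b = usable[b]
            res = stats.mannwhitneyu(d_a, d_b, alternative="two-sided")
            rows.append({
                "sector_a": name_a, "sector_b": name_b,
                "U": float(res.statistic), "p": float(res.pvalue),
                "median_a": float(np.median(d_a)),
                "median_b": float(np.median(d_b)),
                "stars": significance_stars(res.pvalue),
            })
    return pd.DataFrame(rows, columns=["sector_a", "sector_b", "U", "p",
                                       "median_a", "median_b", "stars"])


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


def assign_conservation_classes(profile: ConservationProfile,
                                sectors: list) -> list:
    """Label each sector conserved or coevolved.

    A sector is *conserved* iff its median KLD exceeds that of every other
    sector and every pairwise Mann–Whitney p-value against the others is
    <= 1e-4; all remaining sectors are *coevolved*.  Sectors are modified
    in place and returned.
    """
    if len(sectors) < 2:
        for sec in sectors:
            sec.conservation_class = "unassigned"
        return sectors
    table = compare_sector_conservation(profile, sectors)
    medians = {}
    pos_index = {p: i for i, p in enumerate(profile.positions)}
    for sec in sectors:
        medians[sec.name] = np.median([profile.D[pos_index[p]]
                                       for p in sec.positions])
    for sec in sectors:
        others = table[(table.sector_a == sec.name) | (table.sector_b == sec.name)]
        dominates = all(medians[sec.name] > medians[o.name]
                        for o in sectors if o.name != sec.name)
        significant = len(others) == len(sectors) - 1 and (others.p <= 1e-4).all()
        sec.conservation_class = (
            "conserved" if dominates and significant else "coevolved"
        )
    return sectors


def sectors_to_frame(sectors: list) -> pd.DataFrame:
    """Long-form sector table (sector, position_label, loading, class)."""
    rows = []
    for sec in sectors:
        for p in sec.positions:
            rows.append({"sector": sec.name, "position_label": p,
                         "loading": sec.loadings.get(p, np.nan),
                         "conservation_class": sec.conservation_class})
    return pd.DataFrame(rows, columns=["sector", "position_label", "loading",
                                       "conservation_class"])
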