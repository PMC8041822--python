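"""Subtype amino-acid pattern classification for receptor/G-alpha position pairs.

For one (receptor position, G-alpha position) pair, the rows of the
concatenated alignment are split by coupled G-alpha family, giving four
21 x 21 joint amino-acid frequency matrices (20 residues plus gap, fixed
alphabet order).  Each matrix is flattened row-major into a length-441
vector; the six pairwise cosine similarities between the four vectors are
thresholded (default 0.6) to build a similarity graph on the families, and
the connected components of that graph give the pattern class — one of
the 15 set partitions of a 4-element set (identical patterns in all four
families at one extreme, four different patterns at the other).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .alignment import ALPHABET, N_SYMBOLS
from .integrated import (G_FAMILIES, GALPHA_PREFIX, RECEPTOR_PREFIX,
                         ConcatenatedAlignment)

VECTOR_LENGTH = N_SYMBOLS * N_SYMBOLS  # 441
DEFAULT_SIMILARITY_THRESHOLD = 0.6


@dataclass
class PatternCell:
    """One grid cell: four family-conditioned joint matrices + classification."""

    r_pos: str
    g_pos: str
    freqs: dict                 # family -> (21, 21) ndarray or None if empty
    similarities: dict          # frozenset({fam_a, fam_b}) -> float
    theta_sim: float
    partition: tuple            # tuple of tuples of family names
    missing_families: tuple = ()

    @property
    def partition_code(self) -> str:
        return partition_code(self.partition)


def _family_key(fam: str) -> int:
    return G_FAMILIES.index(fam)


def canonical_partition(blocks) -> tuple:
    """Partition as a tuple of tuples, families in fixed order within and
    across blocks."""
    ordered = [tuple(sorted(b, key=_family_key)) for b in blocks]
    return tuple(sorted(ordered, key=lambda b: _family_key(b[0])))


def partition_code(partition) -> str:
    return "|".join("+".join(block) for block in partition)


def all_partitions(items=G_FAMILIES) -> list:
    """Every set partition of the given items (15 for four families)."""
    items = list(items)
    if not items:
        return [()]
    head, rest = items[0], items[1:]
    out = []
    for sub in all_partitions(rest):
        out.append(canonical_partition(list(sub) + [(head,)]))
        for i, block in enumerate(sub):
            blocks = list(sub)
            blocks[i] = tuple(block) + (head,)
            out.append(canonical_partition(blocks))
    return sorted(set(out))


def subtype_pair_frequencies(concat: ConcatenatedAlignment, r_pos: str,
                             g_pos: str) -> dict:
    """Four family-conditioned 21x21 joint frequency matrices for one pair.

    ``F[a][b]`` is the fraction of that family's rows carrying symbol a at
    the receptor position and symbol b at the G-alpha position.  Families
    with zero rows map to ``None``.
    """
    r_label = r_pos if r_pos.startswith(RECEPTOR_PREFIX) else RECEPTOR_PREFIX + r_pos
    g_label = g_pos if g_pos.startswith(GALPHA_PREFIX) else GALPHA_PREFIX + g_pos
    if r_pos.startswith(GALPHA_PREFIX) or g_pos.startswith(RECEPTOR_PREFIX):
        raise ValueError(
            "need one receptor position and one G-alpha position, in that order")
    labels = concat.aln.position_labels
    idx = concat.aln.to_indices()
    try:
        ri, gi = labels.index(r_label), labels.index(g_label)
    except ValueError as err:
        raise KeyError(f"position not in concatenated alignment: {err}")
    fam_per_row = concat.provenance["g_family"].values
    out = {}
    for fam in G_FAMILIES:
        rows = np.nonzero(fam_per_row == fam)[0]
        if rows.size == 0:
            out[fam] = None
            continue
        F = np.zeros((N_SYMBOLS, N_SYMBOLS))
        np.add.at(F, (idx[rows, ri], idx[rows, gi]), 1.0)
        out[fam] = F / rows.size
    return out


def pattern_similarity(F_a: np.ndarray, F_b: np.ndarray,
                       normalized: bool = True) -> float:
    """Inner product of the flattened 441-vectors; cosine by default.

    With L2 normalization the value lands in [0, 1] (entries are
    non-negative), which makes a single threshold meaningful across cells;
    the raw dot product is available with ``normalized=False``.
    """
    va = np.asarray(F_a, dtype=float).ravel()
    vb = np.asarray(F_b, dtype=float).ravel()
    if va.size != VECTOR_LENGTH or vb.size != VECTOR_LENGTH:
        raise ValueError(f"matrices must flatten to length {VECTOR_LENGTH}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero matrix has no defined pattern similarity")
    if not normalized:
        return float(va @ vb)
    return float(va @ vb / (na * nb))


def classify_pattern(similarities: dict, theta_sim: float = DEFAULT_SIMILARITY_THRESHOLD,
                     families=G_FAMILIES) -> tuple:
    """Connected components of the thresholded similarity graph.

    An edge joins two families when their similarity is >= theta_sim;
    intransitive similarity (A~B, B~C, A!~C) resolves by component closure,
    the only deterministic rule mapping all 64 edge configurations onto the
    15 partitions.  Families missing from ``families`` (e.g. with no rows)
    are simply absent from the partition.
    """
    families = list(families)
    parent = {f: f for f in families}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair, s in similarities.items():
        a, b = sorted(pair, key=_family_key)
        if a in parent and b in parent and s >= theta_sim:
            parent[find(a)] = find(b)
    blocks = {}
    for f in families:
        blocks.setdefault(find(f), []).append(f)
    return canonical_partition(blocks.values())


def make_pattern_cell(concat: ConcatenatedAlignment, r_pos: str, g_pos: str,
                      theta_sim: float = DEFAULT_SIMILARITY_THRESHOLD) -> PatternCell:
    """Frequencies, six similarities and the partition for one position pair."""
    freqs = subtype_pair_frequencies(concat, r_pos, g_pos)
    present = [f for f in G_FAMILIES if freqs[f] is not None]
    missing = tuple(f for f in G_FAMILIES if freqs[f] is None)
    sims = {}
    for fa, fb in combinations(present, 2):
        sims[frozenset((fa, fb))] = pattern_similarity(freqs[fa], freqs[fb])
    partition = classify_pattern(sims, theta_sim, families=present)
    return PatternCell(r_pos=r_pos, g_pos=g_pos, freqs=freqs,
                       similarities=sims, theta_sim=theta_sim,
                       partition=partition, missing_families=missing)


def pattern_map(concat: ConcatenatedAlignment, receptor_positions,
                galpha_positions,
                theta_sim: float = DEFAULT_SIMILARITY_THRESHOLD):
    """PatternCell grid over all (receptor, G-alpha) sector position pairs.

    Returns the |receptor| x |G-alpha| grid (list of lists) and a Counter
    over partition codes summarizing the class histogram.
    """
    if not receptor_positions or not galpha_positions:
        raise ValueError("both sectors must be non-empty")
    grid = []
    histogram = Counter()
    for r_pos in receptor_positions:
        row = []
        for g_pos in galpha_positions:
            cell = make_pattern_cell(concat, r_pos, g_pos, theta_sim)
            histogram[cell.partition_code] += 1
            row.append(cell)
        grid.append(row)
    return grid, histogram


def pattern_table(grid) -> pd.DataFrame:
    """Long-form table: one row per cell with the six similarities."""
    pair_cols = ["s_" + "_".join(sorted(p, key=_family_key)).replace("/", "")
                 for p in map(tuple, combinations(G_FAMILIES, 2))]
    rows = []
    for row in grid:
        for cell in row:
            rec = {"r_pos": cell.r_pos, "g_pos": cell.g_pos}
            for pair, col in zip(combinations(G_FAMILIES, 2), pair_cols):
                rec[col] = cell.similarities.get(frozenset(pair), np.nan)
            rec["partition"] = cell.partition_code
            rec["missing_families"] = "+".join(cell.missing_families)
            rows.append(rec)
    return pd.DataFrame(rows)


def cell_frequencies_long(cell: PatternCell) -> pd.DataFrame:
    """Per-cell joint frequencies in long form (family, r_aa, g_aa, freq)."""
    rows = []
    for fam in G_FAMILIES:
        F = cell.freqs.get(fam)
        if F is None:
            continue
        nz = np.nonzero(F)
        for a, b in zip(*nz):
            rows.append({"g_family": fam, "r_aa": ALPHABET[a],
                         "g_aa": ALPHABET[b], "freq": float(F[a, b])})
    return pd.DataFrame(rows, columns=["g_family", "r_aa", "g_aa", "freq"])


def logo_frequencies(concat: ConcatenatedAlignment, positions) -> pd.DataFrame:
    """Per-position, per-family marginal residue frequencies.

    Long-form table consumable by sequence-logo renderers (one row per
    position x family x symbol with its frequency).
    """
    labels = concat.aln.position_labels
    idx = concat.aln.to_indices()
    fam_per_row = concat.provenance["g_family"].values
    rows = []
    for pos in positions:
        full = pos if pos in labels else (
            RECEPTOR_PREFIX + pos if RECEPTOR_PREFIX + pos in labels
            else GALPHA_PREFIX + pos)
        if full not in labels:
            raise KeyError(f"position '{pos}' not in concatenated alignment")
        col = labels.index(full)
        for fam in G_FAMILIES:
            sel = np.nonzero(fam_per_row == fam)[0]
            if sel.size == 0:
                continue
            counts = np.bincount(idx[sel, col], minlength=N_SYMBOLS)
            freqs = counts / sel.size
            for a, f in enumerate(freqs):
                if f > 0:
                    rows.append({"position": pos, "g_family": fam,
                                 "symbol": ALPHABET[a], "freq": float(f)})
    return pd.DataFrame(rows, columns=["position", "g_family", "symbol", "freq"])
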