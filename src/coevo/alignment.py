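"""Labeled multiple sequence alignments: IO, filtering, weighting, overlap.

An alignment here is a character matrix over the fixed 21-symbol alphabet
``ARNDCQEGHILKMFPSTWYV-`` (20 residues plus gap), with one *position label*
per column (a GPCRdb generic number such as ``"3.50"`` for receptors, or a
CGN label such as ``"G.H5.23"`` for G-alpha subunits) and per-sequence
metadata (subtype, species, protein family).  Position labels are opaque
strings: they travel with their columns through filtering and
concatenation, but are never parsed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed symbol order used everywhere matrices are indexed.
ALPHABET = "ARNDCQEGHILKMFPSTWYV-"
GAP = "-"
N_SYMBOLS = len(ALPHABET)  # 21
_SYM_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}

META_COLUMNS = ("subtype", "species", "protein_family")


@dataclass
class LabeledAlignment:
    """Sequences x positions character matrix with labels and metadata.

    Attributes
    ----------
    seq_ids : list of str
        Unique sequence identifiers, one per row.
    matrix : ndarray of shape (n_seq, n_pos), dtype '<U1'
        Alignment symbols, all members of :data:`ALPHABET`.
    position_labels : list of str
        Unique, order-preserving column labels.
    seq_meta : pandas.DataFrame
        Indexed by seq_id with columns subtype, species, protein_family.
    """

    seq_ids: list
    matrix: np.ndarray
    position_labels: list
    seq_meta: pd.DataFrame

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-dimensional")
        n_seq, n_pos = self.matrix.shape
        if len(self.seq_ids) != n_seq:
            raise ValueError("seq_ids length does not match matrix rows")
        if len(self.position_labels) != n_pos:
            raise ValueError(
                f"{len(self.position_labels)} position labels for {n_pos} columns"
            )
        if len(set(self.position_labels)) != n_pos:
            raise ValueError("position labels must be unique")
        bad = set(np.unique(self.matrix)) - set(ALPHABET)
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")

    @property
    def n_seq(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pos(self) -> int:
        return self.matrix.shape[1]

    def to_indices(self) -> np.ndarray:
        """Integer-encoded matrix (n_seq, n_pos) over the alphabet order."""
        lut = np.zeros(128, dtype=np.int8)
        for c, i in _SYM_TO_IDX.items():
            lut[ord(c)] = i
        return lut[self.matrix.view(np.uint32).astype(np.intp) & 0x7F]

    def subset(self, seq_mask=None, pos_mask=None) -> "LabeledAlignment":
        """New alignment restricted to the given boolean/integer selections."""
        seq_mask = slice(None) if seq_mask is None else seq_mask
        pos_mask = slice(None) if pos_mask is None else pos_mask
        ids = list(np.asarray(self.seq_ids, dtype=object)[seq_mask])
        labels = list(np.asarray(self.position_labels, dtype=object)[pos_mask])
        return LabeledAlignment(
            seq_ids=ids,
            matrix=self.matrix[seq_mask][:, pos_mask],
            position_labels=labels,
            seq_meta=self.seq_meta.loc[ids].copy(),
        )

    def select_positions(self, labels) -> "LabeledAlignment":
        """Restrict to the given position labels, in the given order."""
        index = {p: i for i, p in enumerate(self.position_labels)}
        missing = [p for p in labels if p not in index]
        if missing:
            raise KeyError(f"positions not in alignment: {missing}")
        return self.subset(pos_mask=[index[p] for p in labels])


@dataclass
class SequenceWeights:
    """Per-sequence down-weighting of redundant sequences.

    ``w_s = 1 / |{s' : identity(s, s') >= theta_id}|`` so a cluster of m
    near-identical sequences contributes total weight 1.  ``M_eff`` is the
    effective number of independent sequences.
    """

    w_s: np.ndarray
    M_eff: float
    identity_threshold: float

    def __post_init__(self):
        self.w_s = np.asarray(self.w_s, dtype=float)
        if np.any(self.w_s <= 0) or np.any(self.w_s > 1):
            raise ValueError("sequence weights must lie in (0, 1]")

    @classmethod
    def uniform(cls, n_seq: int) -> "SequenceWeights":
        return cls(np.ones(n_seq), float(n_seq), 0.0)


@dataclass
class OverlapReport:
    """Venn-style overlap between two position-label sets."""

    set_a_only: int
    set_b_only: int
    shared: int
    fraction_of_a: float
    fraction_of_b: float

    def swapped(self) -> "OverlapReport":
        return OverlapReport(
            self.set_b_only, self.set_a_only, self.shared,
            self.fraction_of_b, self.fraction_of_a,
        )


def read_alignment(fasta_path, labels_path, meta_path) -> LabeledAlignment:
    """Read a FASTA alignment plus label and metadata CSVs.

    Symbols outside the 21-letter alphabet (e.g. ``X``, ``B``) are replaced
    by the gap character; the substitution count is logged.  A ragged
    alignment or a label count that does not match the column count is a
    hard error; sequences missing from the metadata get empty fields with a
    warning.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        ref = len(records[0].seq)
        for r in records:
            if len(r.seq) != ref:
                raise ValueError(
                    f"ragged alignment: sequence '{r.id}' has length "
                    f"{len(r.seq)}, expected {ref}"
                )
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    known = np.isin(matrix, list(ALPHABET))
    n_subst = int((~known).sum())
    if n_subst:
        logger.info("replaced %d non-alphabet symbols with gap", n_subst)
        matrix[~known] = GAP

    labels_df = pd.read_csv(labels_path, dtype=str)  # "3.50" stays a string
    labels = [str(x) for x in labels_df["label"]]
    if len(labels) != matrix.shape[1]:
        raise ValueError(
            f"{len(labels)} labels for {matrix.shape[1]} alignment columns"
        )

    meta_df = pd.read_csv(meta_path, dtype=str).set_index("seq_id")
    seq_ids = [r.id for r in records]
    meta = pd.DataFrame(index=pd.Index(seq_ids, name="seq_id"),
                        columns=list(META_COLUMNS), dtype=object)
    for sid in seq_ids:
        if sid in meta_df.index:
            row = meta_df.loc[sid]
            for col in META_COLUMNS:
                meta.loc[sid, col] = row.get(col, "")
        else:
            warnings.warn(f"no metadata for sequence '{sid}'; fields left empty")
            meta.loc[sid] = ""
    meta = meta.fillna("")
    return LabeledAlignment(seq_ids, matrix, labels, meta)


def write_alignment(aln: LabeledAlignment, fasta_path, labels_path, meta_path) -> None:
    """Write an alignment back to FASTA + label CSV + metadata CSV."""
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.seq_ids, aln.matrix)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {"column_index": range(aln.n_pos), "label": aln.position_labels}
    ).to_csv(labels_path, index=False)
    aln.seq_meta.reset_index().rename(columns={"index": "seq_id"}).to_csv(
        meta_path, index=False
    )


def preprocess_alignment(aln: LabeledAlignment, max_pos_gap: float = 0.2,
                         max_seq_gap: float = 0.2):
    """Drop gap-heavy columns and sequences; iterate to a fixed point.

    Positions with gap fraction above ``max_pos_gap`` are removed, then
    sequences with gap fraction above ``max_seq_gap``; because each removal
    changes the other axis's gap fractions, the two steps repeat until
    nothing changes, which makes the operation idempotent.

    Returns
    -------
    (LabeledAlignment, dict)
        The filtered alignment and a report with the removed labels/ids.
    """
    for frac, name in ((max_pos_gap, "max_pos_gap"), (max_seq_gap, "max_seq_gap")):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    current = aln
    removed_positions, removed_sequences = [], []
    while True:
        is_gap = current.matrix == GAP
        if current.n_seq == 0 or current.n_pos == 0:
            raise ValueError("alignment empty after gap filtering")
        pos_keep = is_gap.mean(axis=0) <= max_pos_gap
        if not pos_keep.all():
            removed_positions += [
                p for p, k in zip(current.position_labels, pos_keep) if not k
            ]
            current = current.subset(pos_mask=pos_keep)
            if current.n_pos == 0:
                raise ValueError("alignment empty after gap filtering")
        is_gap = current.matrix == GAP
        seq_keep = is_gap.mean(axis=1) <= max_seq_gap
        if not seq_keep.all():
            removed_sequences += [
                s for s, k in zip(current.seq_ids, seq_keep) if not k
            ]
            current = current.subset(seq_mask=seq_keep)
            if current.n_seq == 0:
                raise ValueError("alignment empty after gap filtering")
        if pos_keep.all() and seq_keep.all():
            break
    report = {
        "removed_positions": removed_positions,
        "removed_sequences": removed_sequences,
        "max_pos_gap": max_pos_gap,
        "max_seq_gap": max_seq_gap,
    }
    return current, report


def compute_sequence_weights(aln: LabeledAlignment,
                             identity_threshold: float = 0.8) -> SequenceWeights:
    """Down-weight redundant sequences by neighborhood size.

    Pairwise identity is the fraction of matching symbols over the full
    alignment length (gap-vs-gap counts as a match).  Each sequence gets
    weight ``1/n`` where ``n`` counts sequences (itself included) at or
    above the identity threshold.
    """
    if aln.n_seq < 1:
        raise ValueError("empty alignment")
    idx = aln.to_indices()
    n = aln.n_seq
    counts = np.zeros(n, dtype=np.int64)
    # chunked pairwise identity; memory stays ~chunk * n * n_pos bytes
    chunk = max(1, int(2e7 // max(1, n * aln.n_pos)))
    for start in range(0, n, chunk):
        block = idx[start:start + chunk]  # (c, n_pos)
        ident = (block[:, None, :] == idx[None, :, :]).mean(axis=2)
        counts[start:start + chunk] = (ident >= identity_threshold).sum(axis=1)
    w = 1.0 / counts
    return SequenceWeights(w, float(w.sum()), identity_threshold)


def position_set_overlap(set_a, set_b) -> OverlapReport:
    """Exact set arithmetic between two position-label collections."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        warnings.warn("overlap requested with an empty position set")
    shared = len(a & b)
    return OverlapReport(
        set_a_only=len(a - b),
        set_b_only=len(b - a),
        shared=shared,
        fraction_of_a=shared / len(a) if a else 0.0,
        fraction_of_b=shared / len(b) if b else 0.0,
    )
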