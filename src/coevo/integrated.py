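"""Coupling-aware concatenated receptor–G-alpha alignments and cross-sector SCA.

To measure coevolution *between* a receptor family and the G-alpha
subunits it signals through, receptor sequences are joined to G-alpha
sequences family-by-family: each receptor sequence contributes one
concatenated row per primary-coupled G-alpha family of its subtype (a
dually coupled subtype, e.g. one signaling through both Gi/o and Gq/11,
appears once per family).  The coupling matrix over the concatenated
sector columns is computed with the standard SCA formula but without noise
cleaning or clustering — the sectors are already defined, and the object
of interest is the receptor x G-alpha off-diagonal block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, LabeledAlignment, SequenceWeights
from .sca import (CouplingMatrix, background_frequencies, coupling_matrix,
                  estimate_frequencies)

logger = logging.getLogger(__name__)

#: fixed G-alpha family order used in all outputs
G_FAMILIES = ("Gi/o", "Gq/11", "Gs", "G12/13")

RECEPTOR_PREFIX = "R:"
GALPHA_PREFIX = "G:"


@dataclass
class CouplingTable:
    """Receptor-subtype → G-alpha-family coupling annotations."""

    table: pd.DataFrame  # columns: receptor_subtype, g_family, primary

    def __post_init__(self):
        required = {"receptor_subtype", "g_family", "primary"}
        if not required <= set(self.table.columns):
            raise ValueError(f"coupling table needs columns {sorted(required)}")
        bad = set(self.table.g_family) - set(G_FAMILIES)
        if bad:
            raise ValueError(
                f"unknown g_family values {sorted(bad)}; accepted: {list(G_FAMILIES)}"
            )
        dup = self.table.duplicated(["receptor_subtype", "g_family"])
        if dup.any():
            pairs = self.table.loc[dup, ["receptor_subtype", "g_family"]]
            raise ValueError(f"duplicate coupling rows: {pairs.values.tolist()}")

    def primary_families(self, subtype: str) -> list:
        rows = self.table[(self.table.receptor_subtype == subtype)
                          & self.table.primary]
        fams = list(rows.g_family)
        return sorted(fams, key=G_FAMILIES.index)

    @property
    def subtypes(self) -> list:
        return list(self.table.receptor_subtype.unique())

    def subtypes_without_primary(self) -> list:
        return [s for s in self.subtypes if not self.primary_families(s)]


@dataclass
class ConcatenatedAlignment:
    """Receptor sector columns joined to G-alpha sector columns, per row.

    ``boundary`` is the number of receptor columns; ``provenance`` records,
    per row, the receptor sequence, the G-alpha partner (or the family
    consensus) and the coupled family.
    """

    aln: LabeledAlignment
    provenance: pd.DataFrame  # receptor_seq_id, galpha_seq_id, g_family, species
    boundary: int

    def receptor_block(self) -> LabeledAlignment:
        return self.aln.subset(pos_mask=np.arange(self.boundary))

    def galpha_block(self) -> LabeledAlignment:
        return self.aln.subset(pos_mask=np.arange(self.boundary, self.aln.n_pos))


def load_coupling_table(path) -> CouplingTable:
    """Read a (receptor_subtype, g_family, primary) CSV.

    Non-primary rows are kept but flagged; subtypes lacking any primary
    coupling are reported with a warning.
    """
    df = pd.read_csv(path)
    df["primary"] = df["primary"].astype(str).str.lower().isin(
        ("true", "1", "yes", "t"))
    table = CouplingTable(df.reset_index(drop=True))
    orphans = table.subtypes_without_primary()
    if orphans:
        warnings.warn(f"subtypes without any primary coupling: {orphans}")
    return table


def _family_consensus(galpha_aln: LabeledAlignment, family: str) -> np.ndarray:
    rows = galpha_aln.seq_meta["protein_family"] == family
    block = galpha_aln.matrix[np.asarray(rows)]
    cons = np.empty(block.shape[1], dtype="<U1")
    for j in range(block.shape[1]):
        symbols, counts = np.unique(block[:, j], return_counts=True)
        cons[j] = symbols[np.argmax(counts)]
    return cons


def build_concatenated_alignment(receptor_aln: LabeledAlignment,
                                 galpha_aln: LabeledAlignment,
                                 coupling: CouplingTable,
                                 receptor_positions,
                                 galpha_positions,
                                 pairing_policy: str = "species-consensus"
                                 ) -> ConcatenatedAlignment:
    """Join receptor and G-alpha sector columns per primary coupling.

    For each receptor sequence and each primary-coupled family of its
    subtype, one row is emitted pairing the receptor's sector columns with
    those of a G-alpha sequence of that family.  The partner is the
    same-species sequence when one exists; under the default
    ``"species-consensus"`` policy a missing same-species partner falls
    back to the family consensus sequence, while ``"species-strict"``
    drops the row with a warning.
    """
    if pairing_policy not in ("species-consensus", "species-strict"):
        raise ValueError("pairing_policy must be species-consensus or species-strict")
    r_sub = receptor_aln.select_positions(list(receptor_positions))
    g_sub = galpha_aln.select_positions(list(galpha_positions))

    fam_col = g_sub.seq_meta["protein_family"]
    fam_members = {fam: [i for i, sid in enumerate(g_sub.seq_ids)
                         if fam_col.loc[sid] == fam] for fam in G_FAMILIES}
    needed = {fam for s in coupling.subtypes for fam in coupling.primary_families(s)}
    for fam in needed:
        if not fam_members[fam]:
            raise ValueError(f"no G-alpha sequences annotated to family '{fam}'")
    by_species = {}
    for fam, idxs in fam_members.items():
        by_species[fam] = {}
        for i in idxs:
            sp = g_sub.seq_meta["species"].iloc[i]
            by_species[fam].setdefault(sp, i)  # first sequence per species
    consensus = {}

    rows, ids, prov = [], [], []
    known_subtypes = set(coupling.subtypes)
    skipped_subtypes = set()
    for r_idx, rid in enumerate(r_sub.seq_ids):
        subtype = r_sub.seq_meta["subtype"].loc[rid]
        species = r_sub.seq_meta["species"].loc[rid]
        if subtype not in known_subtypes:
            skipped_subtypes.add(subtype)
            continue
        for fam in coupling.primary_families(subtype):
            partner_idx = by_species[fam].get(species)
            if partner_idx is not None:
                g_row = g_sub.matrix[partner_idx]
                g_id = g_sub.seq_ids[partner_idx]
            elif pairing_policy == "species-consensus":
                if fam not in consensus:
                    consensus[fam] = _family_consensus(g_sub, fam)
                g_row = consensus[fam]
                g_id = f"consensus:{fam}"
                logger.info("no %s G-alpha for species %s; using family consensus",
                            fam, species)
            else:
                warnings.warn(
                    f"receptor '{rid}' ({species}) has no {fam} partner; row dropped")
                continue
            rows.append(np.concatenate([r_sub.matrix[r_idx], g_row]))
            ids.append(f"{rid}|{fam.replace('/', '')}")
            prov.append({"receptor_seq_id": rid, "galpha_seq_id": g_id,
                         "g_family": fam, "species": species})
    if skipped_subtypes:
        warnings.warn(
            f"receptor subtypes absent from coupling table, rows skipped: "
            f"{sorted(skipped_subtypes)}")
    if not rows:
        raise ValueError("concatenation produced no rows")

    labels = ([RECEPTOR_PREFIX + p for p in r_sub.position_labels]
              + [GALPHA_PREFIX + p for p in g_sub.position_labels])
    prov_df = pd.DataFrame(prov)
    meta = pd.DataFrame({
        "subtype": [r_sub.seq_meta["subtype"].loc[p["receptor_seq_id"]]
                    for p in prov],
        "species": prov_df["species"].values,
        "protein_family": prov_df["g_family"].values,
    }, index=pd.Index(ids, name="seq_id"))
    aln = LabeledAlignment(ids, np.array(rows), labels, meta)
    return ConcatenatedAlignment(aln=aln, provenance=prov_df,
                                 boundary=r_sub.n_pos)


def cross_sector_coupling(concat: ConcatenatedAlignment,
                          weights: SequenceWeights | None = None,
                          lambda_pc: float = 0.03,
                          q: np.ndarray | None = None):
    """Full coupling matrix over concatenated columns plus the cross block.

    No noise cleaning and no clustering: every sector column is kept so the
    covariances between already defined sectors stay observable.  Returns
    the full :class:`CouplingMatrix` and the receptor x G-alpha block as a
    DataFrame (receptor labels as rows, G-alpha labels as columns, prefixes
    stripped).
    """
    q = background_frequencies() if q is None else q
    aln = concat.aln
    weights = weights or SequenceWeights.uniform(aln.n_seq)
    freqs = estimate_frequencies(aln, weights, lambda_pc=lambda_pc, q=q)
    C = coupling_matrix(aln, weights, freqs)
    b = concat.boundary
    block = pd.DataFrame(
        C.values[:b, b:],
        index=[p[len(RECEPTOR_PREFIX):] for p in aln.position_labels[:b]],
        columns=[p[len(GALPHA_PREFIX):] for p in aln.position_labels[b:]],
    )
    return C, block
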