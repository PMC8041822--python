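"""Synthetic receptor / G-alpha families with planted coevolution structure.

The generator emulates the statistical features of curated receptor-family
and G-alpha alignments that the pipeline consumes, without imitating real
sequences: subtype-structured rows, highly conserved columns, coevolving
column groups whose residue identity tracks subtype, gap-containing
columns, and *selectivity* columns whose residue identity tracks the
G-alpha family a sequence couples to — the planted inter-protein signal.
Every draw is reproducible from the spec's seed, and a ground-truth
manifest records exactly what was planted.

Default shape loosely mirrors a receptor-subfamily study: 13 receptor
subtypes over four G-alpha families (16 G-alpha genes, four per family),
with sector sizes of a few tens of positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alignment import ALPHABET, GAP, LabeledAlignment
from .integrated import G_FAMILIES, CouplingTable
from .sca import background_frequencies

_RESIDUES = ALPHABET[:-1]  # 20 residues, no gap

#: four genes per family, sixteen G-alpha genes in total
GALPHA_GENES = {
    "Gi/o": ("GNAI1", "GNAI2", "GNAI3", "GNAO1"),
    "Gq/11": ("GNAQ", "GNA11", "GNA14", "GNA15"),
    "Gs": ("GNAS", "GNAL", "GNAS2", "GNASXL"),
    "G12/13": ("GNA12", "GNA13", "GNA12B", "GNA13B"),
}


def _default_coupling_map():
    """13 subtypes round-robin over the four families; one dual coupler.

    Subtype R01 primarily couples to both Gi/o and Gq/11, mirroring
    receptors with two primary transducer families.
    """
    cmap = {}
    for k in range(13):
        name = f"R{k + 1:02d}"
        fam = G_FAMILIES[k % 4]
        cmap[name] = (fam,)
    cmap["R01"] = ("Gi/o", "Gq/11")
    return cmap


def _receptor_labels(n):
    # GPCRdb-style generic numbers: helix.position
    return [f"{1 + i // 15}.{30 + i % 15}" for i in range(n)]


def _galpha_labels(n):
    # CGN-style labels: G.<element>.<index>
    return [f"G.H{1 + i // 20}.{1 + i % 20}" for i in range(n)]


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults are the study conditions."""

    n_subtypes_r: int = 13
    seqs_per_subtype: int = 45
    n_pos_r: int = 100
    n_pos_g: int = 60
    n_conserved_r: int = 10
    n_coevolved_r: int = 20
    n_selectivity_r: int = 4
    n_conserved_g: int = 10
    n_coevolved_g: int = 14
    n_selectivity_g: int = 4
    conservation_strength: float = 0.95
    # subtype-specific positions carry a small set of amino-acid variants
    # (subfamily motifs), not one residue per subtype
    coevolved_n_variants: int = 3
    mutation_noise: float = 0.05
    gap_rate: float = 0.01
    coupling_map: dict = field(default_factory=_default_coupling_map)
    # family blocks sharing a selectivity residue; mirrors the observed
    # Gi/o+G12/13 vs Gq/11+Gs pattern dichotomy
    selectivity_grouping: tuple = (("Gi/o", "G12/13"), ("Gq/11", "Gs"))
    seed: int = 0

    def __post_init__(self):
        for name in ("conservation_strength", "mutation_noise", "gap_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_conserved_r + self.n_coevolved_r + self.n_selectivity_r > self.n_pos_r:
            raise ValueError("receptor structured positions exceed n_pos_r")
        if self.n_conserved_g + self.n_coevolved_g + self.n_selectivity_g > self.n_pos_g:
            raise ValueError("G-alpha structured positions exceed n_pos_g")
        if len(self.coupling_map) != self.n_subtypes_r:
            raise ValueError("coupling_map must cover every receptor subtype")
        for st, fams in self.coupling_map.items():
            if not fams:
                raise ValueError(f"subtype {st} has no primary family")
            bad = set(fams) - set(G_FAMILIES)
            if bad:
                raise ValueError(f"unknown families for {st}: {sorted(bad)}")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    receptor_sectors: dict        # kind -> list of position labels
    galpha_sectors: dict
    selectivity_assignments: dict  # side -> {pos -> {family -> residue}}
    coupling_map: dict
    selectivity_grouping: tuple
    seed: int

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["selectivity_grouping"] = [list(b) for b in
                                           self.selectivity_grouping]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _residue_background(q21: np.ndarray) -> np.ndarray:
    q = q21[:-1].copy()
    return q / q.sum()


def _sample_background(rng, shape, q_res):
    return rng.choice(len(_RESIDUES), size=shape, p=q_res)


def generate_families(spec: SyntheticSpec):
    """Receptor + G-alpha alignments, coupling table and ground truth.

    Column classes:

    * background — i.i.d. residues from the background distribution;
    * conserved — one dominant residue with probability
      ``conservation_strength``, otherwise background;
    * coevolved — residue a random function of subtype (receptor) or gene
      (G-alpha), flipped to a random residue with ``mutation_noise``;
    * selectivity — residue a function of the coupled family's grouping
      block, same noise.

    Gaps are injected uniformly at ``gap_rate``.  Species tags guarantee
    every receptor sequence a same-species G-alpha partner in every family.
    """
    rng = np.random.default_rng(spec.seed)
    q_res = _residue_background(background_frequencies())
    subtypes = list(spec.coupling_map)
    species_pool = [f"sp{k + 1:03d}" for k in range(spec.seqs_per_subtype)]
    block_of = {}
    for block in spec.selectivity_grouping:
        for fam in block:
            block_of[fam] = tuple(block)
    for fam in G_FAMILIES:
        block_of.setdefault(fam, (fam,))

    # --- position bookkeeping (receptor) ---
    r_labels = _receptor_labels(spec.n_pos_r)
    perm_r = rng.permutation(spec.n_pos_r)
    c0 = spec.n_conserved_r
    c1 = c0 + spec.n_coevolved_r
    c2 = c1 + spec.n_selectivity_r
    r_conserved = sorted(perm_r[:c0])
    r_coevolved = sorted(perm_r[c0:c1])
    r_select = sorted(perm_r[c1:c2])

    g_labels = _galpha_labels(spec.n_pos_g)
    perm_g = rng.permutation(spec.n_pos_g)
    d0 = spec.n_conserved_g
    d1 = d0 + spec.n_coevolved_g
    d2 = d1 + spec.n_selectivity_g
    g_conserved = sorted(perm_g[:d0])
    g_coevolved = sorted(perm_g[d0:d1])
    g_select = sorted(perm_g[d1:d2])

    # --- receptor alignment ---
    n_seq_r = spec.n_subtypes_r * spec.seqs_per_subtype
    Ridx = _sample_background(rng, (n_seq_r, spec.n_pos_r), q_res)
    row_subtype = np.repeat(np.arange(spec.n_subtypes_r), spec.seqs_per_subtype)
    row_species = np.tile(np.arange(spec.seqs_per_subtype), spec.n_subtypes_r)

    for j in r_conserved:
        dom = rng.choice(len(_RESIDUES), p=q_res)
        hit = rng.random(n_seq_r) < spec.conservation_strength
        Ridx[hit, j] = dom
    for j in r_coevolved:
        variants = rng.choice(len(_RESIDUES), size=spec.coevolved_n_variants,
                              replace=False)
        m = variants[rng.integers(len(variants), size=spec.n_subtypes_r)]
        Ridx[:, j] = m[row_subtype]
    # receptor selectivity: residue determined by the grouping block of the
    # subtype's first primary family
    rep_family = [spec.coupling_map[s][0] for s in subtypes]
    blocks = sorted({block_of[f] for f in G_FAMILIES},
                    key=lambda b: G_FAMILIES.index(b[0]))
    sel_assign_r = {}
    for j in r_select:
        block_res = dict(zip(
            blocks, rng.choice(len(_RESIDUES), size=len(blocks), replace=False)))
        sel_assign_r[r_labels[j]] = {
            fam: _RESIDUES[block_res[block_of[fam]]] for fam in G_FAMILIES}
        per_subtype = np.array([block_res[block_of[f]] for f in rep_family])
        Ridx[:, j] = per_subtype[row_subtype]
    # mutation noise on structured columns
    structured_r = r_coevolved + r_select
    for j in structured_r:
        flip = rng.random(n_seq_r) < spec.mutation_noise
        Ridx[flip, j] = _sample_background(rng, flip.sum(), q_res)

    r_matrix = np.array(list(_RESIDUES))[Ridx]
    gap_mask = rng.random(r_matrix.shape) < spec.gap_rate
    r_matrix[gap_mask] = GAP
    r_ids = [f"{subtypes[row_subtype[s]]}_{species_pool[row_species[s]]}"
             for s in range(n_seq_r)]
    r_meta = pd.DataFrame({
        "subtype": [subtypes[t] for t in row_subtype],
        "species": [species_pool[sp] for sp in row_species],
        "protein_family": "receptor",
    }, index=pd.Index(r_ids, name="seq_id"))
    receptor_aln = LabeledAlignment(r_ids, r_matrix, r_labels, r_meta)

    # --- G-alpha alignment: one sequence per (family, species) ---
    fam_rows, gene_rows, sp_rows = [], [], []
    for fi, fam in enumerate(G_FAMILIES):
        genes = GALPHA_GENES[fam]
        for k, sp in enumerate(species_pool):
            fam_rows.append(fi)
            gene_rows.append(fi * len(genes) + (k % len(genes)))
            sp_rows.append(sp)
    n_seq_g = len(fam_rows)
    fam_rows = np.array(fam_rows)
    gene_rows = np.array(gene_rows)
    Gidx = _sample_background(rng, (n_seq_g, spec.n_pos_g), q_res)
    for j in g_conserved:
        dom = rng.choice(len(_RESIDUES), p=q_res)
        hit = rng.random(n_seq_g) < spec.conservation_strength
        Gidx[hit, j] = dom
    n_genes = sum(len(v) for v in GALPHA_GENES.values())
    for j in g_coevolved:
        variants = rng.choice(len(_RESIDUES), size=spec.coevolved_n_variants,
                              replace=False)
        m = variants[rng.integers(len(variants), size=n_genes)]
        Gidx[:, j] = m[gene_rows]
    sel_assign_g = {}
    for j in g_select:
        block_res = dict(zip(
            blocks, rng.choice(len(_RESIDUES), size=len(blocks), replace=False)))
        sel_assign_g[g_labels[j]] = {
            fam: _RESIDUES[block_res[block_of[fam]]] for fam in G_FAMILIES}
        per_family = np.array([block_res[block_of[f]] for f in G_FAMILIES])
        Gidx[:, j] = per_family[fam_rows]
    for j in list(g_coevolved) + list(g_select):
        flip = rng.random(n_seq_g) < spec.mutation_noise
        Gidx[flip, j] = _sample_background(rng, flip.sum(), q_res)

    g_matrix = np.array(list(_RESIDUES))[Gidx]
    gap_mask = rng.random(g_matrix.shape) < spec.gap_rate
    g_matrix[gap_mask] = GAP
    gene_names = [g for fam in G_FAMILIES for g in GALPHA_GENES[fam]]
    g_ids = [f"{gene_names[gene_rows[s]]}_{sp_rows[s]}" for s in range(n_seq_g)]
    g_meta = pd.DataFrame({
        "subtype": [gene_names[g] for g in gene_rows],
        "species": sp_rows,
        "protein_family": [G_FAMILIES[f] for f in fam_rows],
    }, index=pd.Index(g_ids, name="seq_id"))
    galpha_aln = LabeledAlignment(g_ids, g_matrix, g_labels, g_meta)

    # --- coupling table ---
    rows = []
    for st in subtypes:
        for fam in G_FAMILIES:
            rows.append({"receptor_subtype": st, "g_family": fam,
                         "primary": fam in spec.coupling_map[st]})
    coupling = CouplingTable(pd.DataFrame(rows))

    truth = GroundTruth(
        receptor_sectors={
            "conserved": [r_labels[j] for j in r_conserved],
            "coevolved": [r_labels[j] for j in r_coevolved],
            "selectivity": [r_labels[j] for j in r_select],
        },
        galpha_sectors={
            "conserved": [g_labels[j] for j in g_conserved],
            "coevolved": [g_labels[j] for j in g_coevolved],
            "selectivity": [g_labels[j] for j in g_select],
        },
        selectivity_assignments={"receptor": sel_assign_r, "galpha": sel_assign_g},
        coupling_map={k: list(v) for k, v in spec.coupling_map.items()},
        selectivity_grouping=spec.selectivity_grouping,
        seed=spec.seed,
    )
    return receptor_aln, galpha_aln, coupling, truth


def generate_null_alignment(n_seq: int, n_pos: int,
                            q: np.ndarray | None = None,
                            seed: int | None = None) -> LabeledAlignment:
    """I.i.d. background-drawn alignment with no planted structure.

    Symbols (gap included) are drawn from the 21-symbol background ``q``;
    used to calibrate the noise-cleaning step.
    """
    if n_seq < 1 or n_pos < 1:
        raise ValueError("n_seq and n_pos must be >= 1")
    q = background_frequencies() if q is None else np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ALPHABET), size=(n_seq, n_pos), p=q / q.sum())
    matrix = np.array(list(ALPHABET))[idx]
    ids = [f"null{k:05d}" for k in range(n_seq)]
    meta = pd.DataFrame({"subtype": "null", "species": "none",
                         "protein_family": "null"},
                        index=pd.Index(ids, name="seq_id"))
    labels = [f"p{j + 1}" for j in range(n_pos)]
    return LabeledAlignment(ids, matrix, labels, meta)
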