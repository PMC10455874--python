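"""Planted-truth synthetic data for every pipeline stage.

Real inputs to the screen are NCBI transcriptome assemblies, BLAST tables
against NCBI protein databases, and Bayesian trees — none of which can be
regenerated offline.  This module fabricates inputs with *known* planted
labels instead: proteins carrying the exact motif layout of each TPPP-like
type, contaminated "transcriptomes" (back-translated contaminants dropped
among random background transcripts under sequential accession-style ids),
best-hit tables with class-dependent identity/coverage bands, and trees with
a query grafted into a known placement class.  Every generator is
deterministic under its seed and emits a truth table for recovery tests.

Background composition is uniform (not empirical); accidental motif matches
in background sequence are possible by design and are measured rather than
suppressed — downstream tests judge recovery against truth labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .motifs import DEFAULT_REFERENCE, ReferenceDomain, TpppType
from .placement import GroupAssignment, Placement
from .screen import BlastRow, Category, HitClassification, TaxonomyMap
from .sequence_io import Alphabet, SequenceRecord

__all__ = [
    "TruthRow",
    "TruthTable",
    "gen_tppp_protein",
    "back_translate",
    "gen_contaminated_transcriptome",
    "gen_blast_table",
    "gen_placement_tree",
    "DEFAULT_TAXONOMY",
    "DEFAULT_CLASS_BANDS",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"


@dataclass(frozen=True)
class TruthRow:
    id: str
    label: str
    seed: int
    params: tuple[tuple[str, str], ...] = ()

    def param(self, key: str) -> str | None:
        return dict(self.params).get(key)


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def label_of(self, id: str) -> str | None:
        for row in self.rows:
            if row.id == id:
                return row.label
        return None

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\tseed\tparams\n")
            for r in self.rows:
                p = ";".join(f"{k}={v}" for k, v in r.params)
                fh.write(f"{r.id}\t{r.label}\t{r.seed}\t{p}\n")


_GENERATABLE = (
    TpppType.long,
    TpppType.short,
    TpppType.truncated,
    TpppType.fungal_type,
    TpppType.apicortin,
)


def _core_for(tppp_type: TpppType, cons: str) -> str:
    """The planted residue layout of each type, cut from the consensus.

    The consensus carries the N-terminal signature at its start and the
    Rossmann nonamer inside its C-terminal quarter, so prefix/suffix cuts
    reproduce the published domain layouts directly.
    """
    n = len(cons)
    tail_start = int(np.floor(n * 0.75))  # boundary residue counts as tail
    if tppp_type is TpppType.long:
        return cons
    if tppp_type is TpppType.fungal_type:
        return cons + cons[tail_start:]
    if tppp_type is TpppType.short:
        return cons[: int(n * 0.75)]
    if tppp_type is TpppType.truncated:
        return cons[: int(n * 0.60)]
    if tppp_type is TpppType.apicortin:
        return cons[int(n * 0.75):]
    raise ValueError(f"cannot generate type {tppp_type}")


def gen_tppp_protein(
    tppp_type: TpppType,
    length: int,
    seed: int,
    ref: ReferenceDomain = DEFAULT_REFERENCE,
    record_id: str | None = None,
) -> tuple[SequenceRecord, TruthRow]:
    """One synthetic protein with the motif layout of ``tppp_type``.

    Background padding is i.i.d. uniform over the 20 amino acids and is
    split randomly between the two ends.  ``length`` must accommodate the
    planted core (and be >= twice the reference length for long and
    fungal-type layouts).
    """
    if tppp_type not in _GENERATABLE:
        raise ValueError(f"cannot generate type {tppp_type}")
    core = _core_for(tppp_type, ref.consensus)
    min_len = len(core)
    if tppp_type in (TpppType.long, TpppType.fungal_type):
        min_len = max(min_len, 2 * len(ref))
    if length < min_len:
        raise ValueError(
            f"length {length} too small for {tppp_type.value} (need >= {min_len})"
        )
    rng = np.random.default_rng(seed)
    pad_total = length - len(core)
    left = int(rng.integers(0, pad_total + 1))
    right = pad_total - left
    residues = (
        "".join(rng.choice(list(AA20), size=left))
        + core
        + "".join(rng.choice(list(AA20), size=right))
    )
    rid = record_id or f"SYNPROT_{tppp_type.value}_{seed}"
    rec = SequenceRecord(id=rid, residues=residues, alphabet=Alphabet.protein)
    truth = TruthRow(
        id=rid,
        label=tppp_type.value,
        seed=seed,
        params=(("length", str(length)), ("core_start", str(left + 1))),
    )
    return rec, truth


_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_by_aa() -> dict[str, list[str]]:
    if not _CODONS_BY_AA:
        table = CodonTable.unambiguous_dna_by_name["Standard"]
        for codon, aa in sorted(table.forward_table.items()):
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
        _CODONS_BY_AA["*"] = sorted(table.stop_codons)
    return _CODONS_BY_AA


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice (standard code)."""
    table = _codons_by_aa()
    codons = []
    for aa in protein.upper():
        options = table.get(aa)
        if options is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def gen_contaminated_transcriptome(
    n_background: int,
    contaminant_spec: Sequence[tuple[TpppType, int]],
    seed: int,
    prefix: str = "SYNT",
    number_width: int = 8,
    start_number: int = 1000001,
    background_length: tuple[int, int] = (400, 800),
    protein_length: int = 340,
    ref: ReferenceDomain = DEFAULT_REFERENCE,
) -> tuple[list[SequenceRecord], dict[str, bool], TruthTable]:
    """A mock transcriptome: background transcripts plus planted contaminants.

    Contaminants are back-translated type-layout proteins (random synonymous
    codons, random strand); all records get sequential accession-style ids
    ``prefix + zero-padded number`` so the window screen applies.  Returns
    the records, a DCX annotation map (true for apicortins), and a truth
    table marking contaminants with their planted type, strand, and protein.
    """
    rng = np.random.default_rng(seed)
    n_contam = sum(c for _, c in contaminant_spec)
    total = n_background + n_contam
    ids = [f"{prefix}{start_number + i:0{number_width}d}" for i in range(total)]
    contam_slots = sorted(
        int(i) for i in rng.choice(total, size=n_contam, replace=False)
    ) if n_contam else []
    slot_types: list[TpppType] = []
    for tppp_type, count in contaminant_spec:
        slot_types.extend([tppp_type] * count)
    records: list[SequenceRecord] = []
    dcx: dict[str, bool] = {}
    truth = TruthTable()
    slot_iter = iter(zip(contam_slots, slot_types))
    next_slot = next(slot_iter, None)
    for i, rid in enumerate(ids):
        if next_slot is not None and i == next_slot[0]:
            tppp_type = next_slot[1]
            length = protein_length if tppp_type in (
                TpppType.long, TpppType.fungal_type
            ) else max(len(ref), 200)
            prot_seed = int(rng.integers(0, 2**31 - 1))
            prot, _ = gen_tppp_protein(tppp_type, length, prot_seed, ref)
            nt = back_translate(prot.residues, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from .sequence_io import reverse_complement

                nt = reverse_complement(nt)
            records.append(SequenceRecord(id=rid, residues=nt, alphabet=Alphabet.nucleotide))
            dcx[rid] = tppp_type is TpppType.apicortin
            truth.rows.append(
                TruthRow(
                    id=rid,
                    label=tppp_type.value,
                    seed=seed,
                    params=(
                        ("strand", strand),
                        ("protein", prot.residues),
                    ),
                )
            )
            next_slot = next(slot_iter, None)
        else:
            length = int(rng.integers(background_length[0], background_length[1] + 1))
            nt = "".join(rng.choice(list(NT4), size=length))
            records.append(SequenceRecord(id=rid, residues=nt, alphabet=Alphabet.nucleotide))
            dcx[rid] = False
    return records, dcx, truth


# species -> (group, category); drawn from taxa reported in contamination
# screens of plant assemblies, so synthetic tables look like real ones.
DEFAULT_TAXONOMY: dict[str, tuple[str, Category]] = {
    "Ziziphus jujuba": ("Streptophyta", Category.self_clade),
    "Carpinus fangiana": ("Streptophyta", Category.self_clade),
    "Betula papyrifera": ("Streptophyta", Category.self_clade),
    "Dactylonectria macrodidyma": ("Ascomycota", Category.fungi),
    "Trichoderma gamsii": ("Ascomycota", Category.fungi),
    "Pseudogymnoascus verrucosus": ("Ascomycota", Category.fungi),
    "Spizellomyces punctatus": ("Chytridiomycota", Category.fungi),
    "Quaeritorhiza haematococci": ("Chytridiomycota", Category.fungi),
    "Sphaerobolus stellatus": ("Basidiomycota", Category.fungi),
    "Globisporangium splendens": ("Oomycota", Category.oomycota),
    "Pythium brassicae": ("Oomycota", Category.oomycota),
    "Tetranychus urticae": ("Arthropoda", Category.animal),
    "Frankliniella occidentalis": ("Arthropoda", Category.animal),
    "Adineta vaga": ("Rotifera", Category.animal),
    "Capitella teleta": ("Annelida", Category.animal),
    "Bodo saltans": ("Euglenozoa", Category.protist),
    "Tetrahymena thermophila": ("Ciliophora", Category.protist),
}


def default_taxonomy_map() -> TaxonomyMap:
    return TaxonomyMap(
        species_to_group={sp: grp for sp, (grp, _) in DEFAULT_TAXONOMY.items()},
        group_to_category={grp: cat for grp, cat in DEFAULT_TAXONOMY.values()},
    )


# identity and coverage bands per planted class; disjoint with respect to the
# default thresholds (evident >= 98, dual rule > 90) so recovery is exact.
DEFAULT_CLASS_BANDS: dict[HitClassification, tuple[tuple[float, float], tuple[float, float]]] = {
    HitClassification.evident_contamination: ((98.0, 100.0), (60.0, 100.0)),
    HitClassification.likely_contamination: ((90.6, 97.4), (90.6, 99.0)),
    HitClassification.candidate_foreign: ((40.0, 75.0), (40.0, 95.0)),
}

_FOREIGN_CLASSES = (
    HitClassification.evident_contamination,
    HitClassification.likely_contamination,
    HitClassification.candidate_foreign,
)


def gen_blast_table(
    contaminant_ids: Sequence[str],
    background_ids: Sequence[str],
    seed: int,
    class_assignment: dict[str, HitClassification] | None = None,
    class_bands: dict | None = None,
    decoy_fraction: float = 0.3,
) -> tuple[list[BlastRow], TaxonomyMap, TruthTable]:
    """A mock best-hit table with planted contamination classes.

    Each contaminant gets one top row drawn from its class's identity and
    coverage band against a random foreign species (plus, for a fraction of
    queries, a lower-bitscore decoy row); background queries get self-clade
    best rows.  Classes default to a seeded round-robin over evident /
    likely / candidate.  Bands straddling the default thresholds are noted
    in the truth table as warnings.
    """
    rng = np.random.default_rng(seed)
    bands = class_bands or DEFAULT_CLASS_BANDS
    tax = default_taxonomy_map()
    foreign_species = [
        sp for sp, (_, cat) in DEFAULT_TAXONOMY.items() if cat is not Category.self_clade
    ]
    self_species = [
        sp for sp, (_, cat) in DEFAULT_TAXONOMY.items() if cat is Category.self_clade
    ]
    if class_assignment is None:
        order = list(_FOREIGN_CLASSES)
        class_assignment = {
            qid: order[i % len(order)] for i, qid in enumerate(contaminant_ids)
        }
    rows: list[BlastRow] = []
    truth = TruthTable()

    def _row(qid: str, species: str, pident: float, qcov: float, bitscore: float) -> BlastRow:
        alen = int(60 + rng.integers(0, 120))
        return BlastRow(
            qseqid=qid,
            sseqid=f"SYN_{species.split()[0][:3].upper()}_{int(rng.integers(10**5, 10**6))}",
            pident=round(pident, 2),
            length=alen,
            mismatch=int(alen * (100 - pident) / 100),
            gapopen=0,
            qstart=1,
            qend=alen,
            sstart=1,
            send=alen,
            evalue=float(10.0 ** -float(rng.integers(20, 120))),
            bitscore=round(bitscore, 1),
            qcov=round(qcov, 1),
            subject_species=species,
        )

    for qid in contaminant_ids:
        cls = class_assignment[qid]
        (ilo, ihi), (clo, chi) = bands[cls]
        warn = _band_straddles(cls, (ilo, ihi), (clo, chi))
        pident = float(rng.uniform(ilo, ihi))
        qcov = float(rng.uniform(clo, chi))
        species = foreign_species[int(rng.integers(0, len(foreign_species)))]
        top = float(rng.uniform(180, 260))
        rows.append(_row(qid, species, pident, qcov, top))
        if rng.random() < decoy_fraction:
            decoy_sp = foreign_species[int(rng.integers(0, len(foreign_species)))]
            rows.append(
                _row(qid, decoy_sp, float(rng.uniform(30, 60)), float(rng.uniform(20, 60)), top - float(rng.uniform(20, 80)))
            )
        params = [("species", species)]
        if warn:
            params.append(("warning", "band straddles thresholds"))
        truth.rows.append(TruthRow(id=qid, label=cls.value, seed=seed, params=tuple(params)))
    for qid in background_ids:
        species = self_species[int(rng.integers(0, len(self_species)))]
        rows.append(
            _row(qid, species, float(rng.uniform(60, 95)), float(rng.uniform(50, 100)), float(rng.uniform(120, 200)))
        )
        truth.rows.append(
            TruthRow(id=qid, label=HitClassification.self.value, seed=seed, params=(("species", species),))
        )
    return rows, tax, truth


def _band_straddles(cls: HitClassification, ident, cov) -> bool:
    from .screen import Thresholds

    th = Thresholds()
    if cls is HitClassification.evident_contamination:
        return ident[0] < th.evident_identity
    if cls is HitClassification.likely_contamination:
        return ident[0] <= th.dual_rule or cov[0] <= th.dual_rule or ident[1] >= th.evident_identity
    return ident[1] > th.dual_rule and cov[1] > th.dual_rule or ident[1] >= th.evident_identity


# ---------------------------------------------------------------------------
# placement trees


def _rand_join(items: list, rng: np.random.Generator) -> object:
    """Random binary topology over ``items`` (leaves or subtrees)."""
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        items.append((a, b))
    return items[0]


def _emit(node, support: str = "1.0") -> str:
    if isinstance(node, tuple):
        inner = ",".join(_emit(c, support) for c in node)
        return f"({inner}){support}"
    return str(node)


def _subtree_nodes(node):
    """All tuple-subtrees and leaves below (and including) ``node``."""
    out = [node]
    if isinstance(node, tuple):
        for c in node:
            out.extend(_subtree_nodes(c))
    return out


def _replace(node, old, new):
    if node is old:
        return new
    if isinstance(node, tuple):
        return tuple(_replace(c, old, new) for c in node)
    return node


def gen_placement_tree(
    placement_class: Placement | str,
    n_context: int,
    seed: int,
    groups: Sequence[str] = ("fungi", "animal"),
    query_label: str = "QUERY_1",
    support: float = 1.0,
) -> tuple[str, GroupAssignment, TruthRow]:
    """A random context tree with the query grafted into a known placement.

    Context leaves are split across ``groups`` (each group gets a pure clade
    of >= 2 leaves, random topology inside and among clades).  The graft
    edge is chosen by class: strictly inside a pure-group clade (nested), on
    a pure-group clade's stem (sister), or above a multi-group subtree
    (outside).  All supports are ``support`` (default 1.0).  Returns the
    Newick string, the leaf->group assignment, and a truth row.
    """
    placement_class = Placement(placement_class)
    if placement_class is Placement.unresolved:
        raise ValueError("cannot plant an unresolved placement")
    if n_context < 4:
        raise ValueError("n_context must be >= 4")
    if len(groups) < 2:
        raise ValueError("need at least two context groups")
    rng = np.random.default_rng(seed)
    # at least 2 leaves per group, remainder spread randomly
    counts = {g: 2 for g in groups}
    for _ in range(n_context - 2 * len(groups)):
        counts[groups[int(rng.integers(0, len(groups)))]] += 1
    clades = {}
    leaf_to_group = {}
    for g in groups:
        labels = [f"{g}_{i + 1}" for i in range(counts[g])]
        for lab in labels:
            leaf_to_group[lab] = g
        clades[g] = _rand_join(labels, rng)
    context = _rand_join(list(clades.values()), rng)
    focal = groups[int(rng.integers(0, len(groups)))]
    if placement_class is Placement.nested:
        # graft below the focal clade root: sibling pure-G, context above has G
        candidates = [n for n in _subtree_nodes(clades[focal]) if n is not clades[focal]]
        target = candidates[int(rng.integers(0, len(candidates)))]
        tree = _replace(context, target, (query_label, target))
    elif placement_class is Placement.sister:
        tree = _replace(context, clades[focal], (query_label, clades[focal]))
    else:  # outside: graft above a subtree spanning >= 2 groups
        multi = [
            n
            for n in _subtree_nodes(context)
            if isinstance(n, tuple)
            and len({leaf_to_group[l] for l in _leaves_of(n)}) >= 2
        ]
        target = multi[int(rng.integers(0, len(multi)))]
        tree = _replace(context, target, (query_label, target))
    newick = _emit(tree, f"{support:g}") + ";"
    assignment = GroupAssignment(leaf_to_group=leaf_to_group, query_set={query_label})
    truth = TruthRow(
        id=query_label,
        label=placement_class.value,
        seed=seed,
        params=(("n_context", str(n_context)), ("focal", focal if placement_class is not Placement.outside else "")),
    )
    return newick, assignment, truth


def _leaves_of(node) -> list[str]:
    if isinstance(node, tuple):
        out = []
        for c in node:
            out.extend(_leaves_of(c))
        return out
    return [str(node)]
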