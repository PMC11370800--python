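"""Readers, writers and sanitizers for the external file formats.

The pipeline consumes five plain-text inputs per gene family: an aligned
FASTA (amino acid or nucleotide), a Newick gene tree, a TSV of selected
codon positions, a TSV phenotype table (species x temperature -> standardized
critical oxygen tension, kPa), and a TSV mapping sequence ids to species.
All user-facing coordinates are 1-based alignment columns; internal arrays
are 0-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "Alignment",
    "GeneTree",
    "SiteRecord",
    "SiteSource",
    "PhenotypeTable",
    "read_alignment",
    "write_alignment",
    "translate_codon_alignment",
    "sanitize_alignment",
    "read_sites",
    "write_sites",
    "read_phenotypes",
    "write_phenotypes",
    "read_tree",
    "write_tree",
]

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_FRAMESHIFT_CHARS = frozenset({"!", "*"})

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment with species resolution.

    Rows are equal-length strings over the amino-acid alphabet plus gap '-'
    and unknown 'X' (or nucleotides before translation).
    """

    ids: list[str]
    rows: list[str]
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.rows:
            length = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != length:
                    raise ValueError(
                        f"ragged alignment: sequence {sid!r} has length "
                        f"{len(row)}, expected {length}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, keep_ids: list[str]) -> "Alignment":
        idx = {sid: k for k, sid in enumerate(self.ids)}
        rows = [self.rows[idx[sid]] for sid in keep_ids]
        species = {sid: self.species_of[sid] for sid in keep_ids if sid in self.species_of}
        return Alignment(ids=list(keep_ids), rows=rows, species_of=species)

    def ungapped_length(self, seq_id: str) -> int:
        return sum(1 for c in self.row(seq_id) if c not in "-X")


@dataclass
class GeneTree:
    """A gene tree with branch lengths, thin wrapper over a dendropy tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def resolve_tips(self, ids: list[str], strip_regex: str | None = None) -> dict[str, str]:
        """Map each tree tip label to a sequence id by exact match after an
        optional strip-regex. Unmatched tips are a hard error: silent pruning
        hides data loss."""
        id_set = set(ids)
        mapping: dict[str, str] = {}
        unmatched = []
        for label in self.tip_labels:
            candidate = re.sub(strip_regex, "", label) if strip_regex else label
            if candidate in id_set:
                mapping[label] = candidate
            else:
                unmatched.append(label)
        if unmatched:
            raise ValueError(f"tree tips not matching any sequence id: {unmatched}")
        return mapping


class SiteSource(str, Enum):
    EPISODIC = "episodic"
    PERVASIVE = "pervasive"
    RANDOM_CONTROL = "random_control"


@dataclass(frozen=True)
class SiteRecord:
    """One selected (or control) codon position, 1-based in alignment space."""

    gene_family: str
    codon: int
    meme_p: float | None = None
    busted_er: float | None = None
    source: SiteSource = SiteSource.EPISODIC

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError(f"codon positions are 1-based, got {self.codon}")
        if self.busted_er is not None and self.busted_er < 0:
            raise ValueError("BUSTED evidence ratio must be >= 0")


@dataclass
class PhenotypeTable:
    """species -> {temperature degC -> standardized P_crit in kPa}."""

    values: dict[str, dict[float, float]]

    @property
    def species(self) -> list[str]:
        return sorted(self.values)

    @property
    def temperatures(self) -> list[float]:
        temps: set[float] = set()
        for per_temp in self.values.values():
            temps.update(per_temp)
        return sorted(temps)

    def pcrit(self, species: str, temperature: float) -> float | None:
        return self.values.get(species, {}).get(temperature)


def _read_id_map(table: str | Path) -> dict[str, str]:
    df = pd.read_csv(table, sep="\t", dtype=str)
    if not {"seq_id", "species"} <= set(df.columns):
        raise ValueError("id map TSV must have columns: seq_id, species")
    return dict(zip(df["seq_id"], df["species"]))


def read_alignment(path: str | Path, table: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA; residues uppercased, '.' and '-' become '-',
    unknown letters become 'X'. `table` is an optional seq_id -> species TSV."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seq = str(rec.seq).upper().replace(".", "-")
        rows.append(seq)
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    species_of = _read_id_map(table) if table is not None else {}
    if species_of:
        missing = [i for i in ids if i not in species_of]
        if missing:
            raise ValueError(f"sequence ids missing from id->species map: {missing}")
        species_of = {i: species_of[i] for i in ids}
    return Alignment(ids=ids, rows=rows, species_of=species_of)


def write_alignment(a: Alignment, fasta_path: str | Path, table_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for sid, row in zip(a.ids, a.rows):
            fh.write(f">{sid}\n{row}\n")
    if table_path is not None:
        pd.DataFrame(
            {"seq_id": a.ids, "species": [a.species_of.get(i, i) for i in a.ids]}
        ).to_csv(table_path, sep="\t", index=False)


def translate_codon_alignment(nt_alignment: Alignment) -> Alignment:
    """Translate a codon-aligned nucleotide alignment to amino acids.

    '---' -> '-'; codons containing 'N' or a partial gap pattern handled as:
    whole-codon gaps only (a codon mixing gap and base is an error); ambiguous
    codons and stop codons become 'X'.
    """
    length = nt_alignment.length
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} is not divisible by 3")
    aa_rows = []
    for sid, row in zip(nt_alignment.ids, nt_alignment.rows):
        aa = []
        for col in range(0, length, 3):
            codon = row[col : col + 3]
            n_gap = codon.count("-")
            if n_gap == 3:
                aa.append("-")
            elif n_gap > 0:
                raise ValueError(
                    f"partial-codon gap in sequence {sid!r} at alignment "
                    f"columns {col + 1}-{col + 3}"
                )
            elif codon in _STOP_CODONS:
                aa.append("X")
            else:
                aa.append(_CODON_TABLE.get(codon, "X"))
        aa_rows.append("".join(aa))
    return Alignment(ids=list(nt_alignment.ids), rows=aa_rows, species_of=dict(nt_alignment.species_of))


def sanitize_alignment(
    a: Alignment, frameshift_chars: frozenset[str] = DEFAULT_FRAMESHIFT_CHARS
) -> tuple[Alignment, int]:
    """Replace frameshift markers and stop symbols with 'X'; any letter that
    is not a canonical residue or gap also becomes 'X' (the configurable
    `frameshift_chars` marker set is thus a documented subset of what gets
    masked). Returns the cleaned alignment and the replacement count.
    Idempotent."""
    n_replaced = 0
    rows = []
    for row in a.rows:
        out = []
        for c in row:
            if c == "-" or c in AA_LETTERS or c == "X":
                out.append(c)
            else:
                out.append("X")
                n_replaced += 1
        rows.append("".join(out))
    return Alignment(ids=list(a.ids), rows=rows, species_of=dict(a.species_of)), n_replaced


def read_sites(path: str | Path, alignment_length: int | None = None) -> list[SiteRecord]:
    """Read the site TSV (`gene_family  codon  meme_p  busted_er  source`).

    Empty meme_p / busted_er cells become None. If `alignment_length` is
    given, codons outside [1, length] raise."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_family", "codon"}
    if not required <= set(df.columns):
        raise ValueError(f"site TSV must have columns {sorted(required)}")
    records = []
    for _, r in df.iterrows():
        codon = int(r["codon"])
        if alignment_length is not None and not (1 <= codon <= alignment_length):
            raise ValueError(
                f"codon {codon} outside alignment of length {alignment_length}"
            )
        meme_p = float(r["meme_p"]) if "meme_p" in df.columns and pd.notna(r.get("meme_p")) else None
        er = float(r["busted_er"]) if "busted_er" in df.columns and pd.notna(r.get("busted_er")) else None
        source = SiteSource(str(r["source"])) if "source" in df.columns and pd.notna(r.get("source")) else SiteSource.EPISODIC
        records.append(SiteRecord(str(r["gene_family"]), codon, meme_p, er, source))
    return records


def write_sites(sites: list[SiteRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_family": [s.gene_family for s in sites],
            "codon": [s.codon for s in sites],
            "meme_p": [s.meme_p for s in sites],
            "busted_er": [s.busted_er for s in sites],
            "source": [s.source.value for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, id_map: dict[str, str] | None = None) -> PhenotypeTable:
    """Read the phenotype TSV (`species  temp_C  pcrit_kPa`).

    Species absent from the id map only warn — a species may lack sequences
    for a given family."""
    df = pd.read_csv(path, sep="\t")
    if not {"species", "temp_C", "pcrit_kPa"} <= set(df.columns):
        raise ValueError("phenotype TSV must have columns: species, temp_C, pcrit_kPa")
    values: dict[str, dict[float, float]] = {}
    for _, r in df.iterrows():
        p = float(r["pcrit_kPa"])
        if p <= 0:
            raise ValueError(f"P_crit must be positive, got {p} for {r['species']}")
        values.setdefault(str(r["species"]), {})[float(r["temp_C"])] = p
    if id_map is not None:
        known = set(id_map.values())
        orphans = sorted(set(values) - known)
        if orphans:
            warnings.warn(
                f"species in phenotype table without sequences: {orphans}",
                stacklevel=2,
            )
    return PhenotypeTable(values=values)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    rows = [
        {"species": sp, "temp_C": t, "pcrit_kPa": p}
        for sp, per_temp in sorted(table.values.items())
        for t, p in sorted(per_temp.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path) -> GeneTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    total = sum(e.length or 0.0 for e in tree.edges())
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    for e in tree.edges():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length in tree")
    return GeneTree(tree=tree)


def write_tree(t: GeneTree, path: str | Path) -> None:
    t.tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)
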