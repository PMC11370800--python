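"""z-descriptor encoding of selected alignment columns.

Each selected codon column is expanded into five numeric features (the
extended z-scales: hydrophobicity, steric bulk, polarity, two electronic
descriptors). Gaps and unknown residues are treated as missing and imputed
with the per-column mean of observed cells, so imputation never shifts a
column's observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import Alignment, SiteRecord, SiteSource

__all__ = [
    "ZScaleTable",
    "SiteFeatureMatrix",
    "load_zscales",
    "filter_truncated",
    "encode_sites",
    "select_random_control_sites",
]

N_DESCRIPTORS = 5
MISSING_RESIDUES = frozenset({"-", "X"})


@dataclass(frozen=True)
class ZScaleTable:
    """Immutable 20 x 5 table of published amino-acid descriptors."""

    values: dict[str, tuple[float, ...]]
    citation: str

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"z-scale table must have 20 amino acids, got {len(self.values)}")
        for aa, v in self.values.items():
            if len(v) != N_DESCRIPTORS or not all(np.isfinite(v)):
                raise ValueError(f"bad z-scale row for {aa}: {v}")

    def __getitem__(self, aa: str) -> tuple[float, ...]:
        return self.values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.values


def load_zscales(path: str | Path | None = None) -> ZScaleTable:
    """Load the shipped Sandberg extended z-scales (or a user TSV
    `aa z1 z2 z3 z4 z5`)."""
    if path is None:
        ref = resources.files("oxysites.data") / "sandberg_zscales.tsv"
        with resources.as_file(ref) as p:
            return load_zscales(p)
    citation = ""
    with open(path) as fh:
        header_lines = [line for line in fh if line.startswith("#")]
    citation = " ".join(line.lstrip("# ").strip() for line in header_lines)
    df = pd.read_csv(path, sep="\t", comment="#")
    values = {
        str(r["aa"]): tuple(float(r[f"z{d}"]) for d in range(1, 6)) for _, r in df.iterrows()
    }
    return ZScaleTable(values=values, citation=citation or str(path))


@dataclass
class SiteFeatureMatrix:
    """sequences x (sites*5) feature matrix, imputed, with provenance mask.

    Column (j, d) holds descriptor d of the residue at the j-th site in
    `site_order` (1-based alignment codons). `observed_mask` marks cells
    that were observed rather than imputed.
    """

    row_ids: list[str]
    site_order: list[int]
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if n != len(self.row_ids) or p != N_DESCRIPTORS * len(self.site_order):
            raise ValueError("feature matrix shape inconsistent with row/site lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values after imputation")

    @property
    def column_names(self) -> list[str]:
        return [
            f"site_{codon}_z{d}"
            for codon in self.site_order
            for d in range(1, N_DESCRIPTORS + 1)
        ]

    def site_of_column(self, col: int) -> int:
        """1-based alignment codon that feature column `col` belongs to."""
        return self.site_order[col // N_DESCRIPTORS]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)


def filter_truncated(
    a: Alignment, fraction: float = 0.5
) -> tuple[Alignment, list[str]]:
    """Drop rows shorter than `fraction` of the median full-length ungapped
    length (truncated paralogs form their own artefactual physicochemical
    group and are removed before encoding).

    The reference length is the median ungapped length of the rows that
    survive the cut, found by iterating the rule to a fixed point starting
    from all rows.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    lengths = {sid: a.ungapped_length(sid) for sid in a.ids}
    kept = list(a.ids)
    while True:
        ref = float(np.median([lengths[sid] for sid in kept]))
        new_kept = [sid for sid in a.ids if lengths[sid] >= fraction * ref]
        if new_kept == kept:
            break
        kept = new_kept
        if not kept:
            raise ValueError("truncation filter removed every sequence")
    removed = [sid for sid in a.ids if sid not in set(kept)]
    return a.subset(kept), removed


def encode_sites(
    a: Alignment, sites: list[SiteRecord], z: ZScaleTable
) -> SiteFeatureMatrix:
    """Score the residues at the selected codons with the five z-descriptors.

    Gap '-' and unknown 'X' residues leave all five cells missing; missing
    cells are filled with the per-column mean of the observed cells.
    """
    if not sites:
        raise ValueError("no sites to encode")
    codons = [s.codon for s in sites]
    for c in codons:
        if not 1 <= c <= a.length:
            raise ValueError(f"codon {c} outside alignment of length {a.length}")
    n = a.n_sequences
    m = len(codons)
    values = np.full((n, m * N_DESCRIPTORS), np.nan)
    for i, row in enumerate(a.rows):
        for j, codon in enumerate(codons):
            res = row[codon - 1]
            if res in MISSING_RESIDUES:
                continue
            if res not in z:
                raise ValueError(f"unscorable residue {res!r} at codon {codon}")
            values[i, j * N_DESCRIPTORS : (j + 1) * N_DESCRIPTORS] = z[res]
    observed = np.isfinite(values)
    col_obs = observed.sum(axis=0)
    if np.any(col_obs == 0):
        bad = sorted({codons[c // N_DESCRIPTORS] for c in np.where(col_obs == 0)[0]})
        raise ValueError(f"sites with zero observed residues: {bad}")
    col_means = np.nanmean(values, axis=0)
    values = np.where(observed, values, col_means)
    return SiteFeatureMatrix(
        row_ids=list(a.ids), site_order=list(codons), values=values, observed_mask=observed
    )


def select_random_control_sites(
    a: Alignment,
    excluded: list[SiteRecord],
    n: int,
    seed: int,
    gene_family: str | None = None,
) -> list[SiteRecord]:
    """Draw `n` distinct non-selected columns uniformly without replacement.

    Eligible columns are those not in `excluded` that carry at least one
    observed (scorable) residue. Reproducible under `seed`.
    """
    family = gene_family or (excluded[0].gene_family if excluded else "control")
    excluded_codons = {s.codon for s in excluded}
    eligible = [
        c
        for c in range(1, a.length + 1)
        if c not in excluded_codons
        and any(row[c - 1] not in MISSING_RESIDUES for row in a.rows)
    ]
    if n > len(eligible):
        raise ValueError(f"requested {n} control sites but only {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible, size=n, replace=False).tolist())
    return [
        SiteRecord(family, int(c), source=SiteSource.RANDOM_CONTROL) for c in chosen
    ]
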