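"""Evolutionary conservation of cavity residues from an MSA.

Per-column conservation is scored with the Schneider entropy: the Shannon
entropy of the amino-acid frequencies in an alignment column, normalised
by ln 20 so the score lies in [0, 1] (0 = perfectly conserved column,
1 = uniform use of all twenty letters).  Gaps are excluded from the
frequencies; an all-gap column is reported as missing.  Structure residues
are mapped onto alignment columns through the reference sequence row, and
the entropies of residues lining a cavity are compared against the
remainder of the protein with a two-sample Kolmogorov–Smirnov test
(asymptotic p-value, default significance 0.005).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AMINO_ACIDS", "Alignment", "EntropyProfile", "ResidueMap",
           "KSResult", "read_alignment", "schneider_entropy",
           "entropy_profile", "map_to_alignment", "ks_compare",
           "cavity_conservation_report"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = {"-", ".", "~"}


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length rows of AA letters + gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("one id per row required")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Letters of 0-based column ``j``."""
        return "".join(row[j] for row in self.rows)

    def row_by_id(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i:i + 60] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (via Biopython)."""
    from Bio import AlignIO

    msa = AlignIO.read(str(path), "fasta")
    return Alignment([rec.id for rec in msa], [str(rec.seq) for rec in msa])


def schneider_entropy(column: Iterable[str], k: int = 20) -> float:
    """Normalised Shannon entropy of one alignment column, in [0, 1].

    ``(-sum_a p_a ln p_a) / ln k`` with frequencies over non-gap letters.
    An all-gap column has no defined frequency and returns NaN.
    """
    letters = [c for c in column if c not in GAP_CHARS]
    if not letters:
        return math.nan
    n = len(letters)
    h = 0.0
    for count in Counter(letters).values():
        p = count / n
        h -= p * math.log(p)
    return h / math.log(k)


@dataclass
class EntropyProfile:
    """Per-column Schneider entropy and effective (non-gap) counts."""

    values: np.ndarray          # (L,), NaN for all-gap columns
    effective_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.effective_counts = np.asarray(self.effective_counts, dtype=np.int64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("entropy values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(1, len(self.values) + 1),
            "entropy": self.values,
            "effective_count": self.effective_counts,
        })


def entropy_profile(alignment: Alignment, normalization: str = "alphabet"
                    ) -> EntropyProfile:
    """Schneider entropy for every column of the alignment.

    ``normalization="alphabet"`` divides by ln 20 regardless of sequence
    count (keeps the scale comparable across MSAs); ``"nseq"`` divides by
    ln min(N, 20).
    """
    if normalization == "alphabet":
        k = 20
    elif normalization == "nseq":
        k = max(min(alignment.n_sequences, 20), 2)
    else:
        raise ValueError("normalization must be 'alphabet' or 'nseq'")
    values, counts = [], []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        non_gap = sum(1 for c in col if c not in GAP_CHARS)
        counts.append(non_gap)
        values.append(schneider_entropy(col, k=k))
    return EntropyProfile(np.array(values), np.array(counts))


class MappingError(ValueError):
    pass


@dataclass
class ResidueMap:
    """Structure residue id → 1-based alignment column (injective)."""

    mapping: dict[int, int]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        cols = list(self.mapping.values())
        if len(set(cols)) != len(cols):
            raise ValueError("residue-to-column mapping must be injective")

    def __getitem__(self, resid: int) -> int:
        return self.mapping[resid]

    def __contains__(self, resid: int) -> bool:
        return resid in self.mapping

    def columns(self, resids: Iterable[int]) -> list[int]:
        return [self.mapping[r] for r in resids]


def map_to_alignment(structure_sequence: str, residue_ids: Sequence[int],
                     reference_row: str,
                     reference_id: str | None = None) -> ResidueMap:
    """Map structure residues onto alignment columns via the reference row.

    The structure sequence must occur contiguously in the ungapped
    reference row; gap columns are skipped.  A letter mismatch raises
    :class:`MappingError` naming the offending residue.
    """
    structure_sequence = structure_sequence.upper()
    if len(structure_sequence) != len(residue_ids):
        raise ValueError("one residue id per structure letter required")
    ungapped = []
    columns = []
    for j, c in enumerate(reference_row.upper()):
        if c not in GAP_CHARS:
            ungapped.append(c)
            columns.append(j + 1)          # 1-based columns
    ungapped = "".join(ungapped)
    n = len(structure_sequence)
    if n == 0:
        raise ValueError("empty structure sequence")
    if n > len(ungapped):
        raise MappingError("structure sequence longer than ungapped reference")

    best_offset, best_score = 0, -1
    for off in range(len(ungapped) - n + 1):
        score = sum(a == b for a, b in zip(structure_sequence,
                                           ungapped[off:off + n]))
        if score == n:
            return ResidueMap({int(r): columns[off + i]
                               for i, r in enumerate(residue_ids)},
                              reference_id)
        if score > best_score:
            best_offset, best_score = off, score
    for i, (a, b) in enumerate(zip(structure_sequence,
                                   ungapped[best_offset:best_offset + n])):
        if a != b:
            raise MappingError(
                f"structure residue {residue_ids[i]} ({a}) does not match "
                f"reference letter {b} at alignment column "
                f"{columns[best_offset + i]}")
    raise MappingError("structure sequence could not be aligned")  # pragma: no cover


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    statistic: float
    pvalue: float
    alpha: float
    reject: bool
    n_group: int
    n_rest: int


def ks_compare(group: Sequence[float], rest: Sequence[float],
               alpha: float = 0.005) -> KSResult:
    """Two-sample KS test of ``group`` vs ``rest`` entropy values.

    D is the supremum ECDF distance; the p-value comes from the asymptotic
    two-sample Kolmogorov distribution with effective size
    n1·n2/(n1+n2).  The null is rejected when p < alpha.
    """
    group = np.asarray(group, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if group.size == 0 or rest.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(group, rest, method="asymp")
    d, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return KSResult(d, p, alpha, p < alpha, group.size, rest.size)


def cavity_conservation_report(profile: EntropyProfile, resmap: ResidueMap,
                               cavity_wall_lists: Mapping[str, Sequence[int]],
                               alpha: float = 0.005) -> dict:
    """Per-cavity conservation summary: entropies, median and KS result.

    Each cavity's wall-residue entropies are tested against the entropies
    of all other mapped residues of the protein.  Unmappable residues are
    listed and excluded with a warning; an empty cavity list is an error.
    The returned dict also carries a per-residue entropy table suitable
    for structure colouring.
    """
    all_resids = sorted(resmap.mapping)
    col_of = resmap.mapping
    ent_of = {r: profile.values[col_of[r] - 1] for r in all_resids}

    report: dict = {"alpha": alpha, "cavities": {}}
    table_rows = []
    for name, resids in cavity_wall_lists.items():
        resids = list(resids)
        if not resids:
            raise ValueError(f"cavity {name!r} has an empty residue list")
        unmapped = [r for r in resids if r not in resmap]
        if unmapped:
            warnings.warn(
                f"cavity {name}: residues {unmapped} not mappable to the "
                "alignment; excluded", stacklevel=2)
        mapped = [r for r in resids if r in resmap]
        if not mapped:
            raise ValueError(f"cavity {name!r} has no mappable residues")
        group = np.array([ent_of[r] for r in mapped])
        group = group[np.isfinite(group)]
        rest_ids = [r for r in all_resids if r not in set(mapped)]
        rest = np.array([ent_of[r] for r in rest_ids])
        rest = rest[np.isfinite(rest)]
        ks = ks_compare(group, rest, alpha=alpha)
        report["cavities"][name] = {
            "residues": mapped, "unmapped": unmapped,
            "entropies": group.tolist(),
            "median_entropy": float(np.median(group)),
            "rest_median_entropy": float(np.median(rest)),
            "ks": ks,
        }
        for r, e in zip(mapped, (ent_of[r] for r in mapped)):
            table_rows.append({"cavity": name, "resid": r,
                               "column": col_of[r], "entropy": e})
    report["residue_table"] = pd.DataFrame(
        table_rows, columns=["cavity", "resid", "column", "entropy"])
    return report
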