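"""Uncorrected p-distances with pairwise deletion.

A site contributes to a pair's distance only when both sequences carry an
unambiguous base (A, C, G or T) there; gaps, N and IUPAC ambiguity codes are
treated as unresolved and excluded per pair (pairwise deletion).  A
complete-deletion mode — dropping every column with any unresolved symbol
before computing all distances — is available for sensitivity checks.

Distances are proportions of mismatched sites among jointly resolved sites,
uncorrected for multiple substitutions.  A pair with zero jointly resolved
sites gets a NaN distance and is flagged, never raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .seq_io import Alignment

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seqs: np.ndarray) -> np.ndarray:
    """Map an ``S1`` matrix to uint8 codes: A,C,G,T → 0..3, unresolved → 4."""
    return _CODE[seqs.view(np.uint8)]


def p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> tuple[float, int]:
    """Uncorrected distance between two equal-length sequences.

    Returns ``(distance, valid_sites)``; distance is NaN when no site is
    jointly resolved.
    """
    a = _as_codes(seq_a)
    b = _as_codes(seq_b)
    if a.shape != b.shape:
        raise DataError("p_distance requires equal-length sequences")
    both = (a < 4) & (b < 4)
    valid = int(both.sum())
    if valid == 0:
        return float("nan"), 0
    mismatches = int(((a != b) & both).sum())
    return mismatches / valid, valid


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        seq = np.frombuffer(seq.upper().encode(), dtype="S1")
    return encode(np.asarray(seq, dtype="S1"))


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair resolved-site counts."""

    ids: list[str]
    d: np.ndarray
    valid_sites: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.valid_sites.shape != (n, n):
            raise DataError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sequence id {exc.args[0]!r}") from None

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        rows = self.index_of(ids)
        keep = set(ids)
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(rows, rows)],
            valid_sites=self.valid_sites[np.ix_(rows, rows)],
            undefined_pairs=[
                p for p in self.undefined_pairs if p[0] in keep and p[1] in keep
            ],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{sid}  {row}\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        d = np.array(rows)
        return cls(ids=ids, d=d, valid_sites=np.zeros_like(d, dtype=int))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tdistance\tvalid_sites\n")
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t"
                        f"{self.d[i, j]:.8f}\t{self.valid_sites[i, j]}\n"
                    )


def distance_matrix(alignment: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs uncorrected p-distances.

    Parameters
    ----------
    deletion : {"pairwise", "complete"}
        Pairwise deletion filters unresolved sites per pair; complete
        deletion first drops every column with any unresolved symbol.
    """
    if alignment.n < 2:
        raise DataError("distance matrix needs at least two sequences")
    codes = encode(alignment.seqs)
    if deletion == "complete":
        codes = codes[:, (codes < 4).all(axis=0)]
        if codes.shape[1] == 0:
            raise DataError("complete deletion removed every column")
    elif deletion != "pairwise":
        raise DataError(f"unknown deletion mode {deletion!r}")
    resolved = (codes < 4)
    n = alignment.n
    d = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=int)
    # Row-wise broadcasting keeps memory at O(N*L) per step.
    for i in range(n - 1):
        both = resolved[i] & resolved[i + 1:]
        v = both.sum(axis=1)
        m = ((codes[i] != codes[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(v > 0, m / np.maximum(v, 1), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
        valid[i, i + 1:] = v
        valid[i + 1:, i] = v
    undefined = [
        (alignment.ids[i], alignment.ids[j])
        for i, j in zip(*np.where(np.triu(np.isnan(d), k=1)))
    ]
    if undefined:
        warnings.warn(
            f"{len(undefined)} sequence pair(s) share no resolved sites",
            stacklevel=2,
        )
    return DistanceMatrix(
        ids=list(alignment.ids), d=d, valid_sites=valid, undefined_pairs=undefined
    )


def group_mean_distance(
    D: DistanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str] | None = None,
) -> float:
    """Mean p-distance across groups, or within one group.

    With two distinct groups, the mean runs over all cross pairs; with one
    group (``group_b`` omitted or identical), over all unordered within-group
    pairs.  NaN pairs are excluded with a warning; the result is NaN if no
    pair is defined.
    """
    a = list(group_a)
    same = group_b is None or set(group_b) == set(a)
    if same:
        if len(a) < 2:
            raise DataError("within-group mean needs at least two members")
        ra = D.index_of(a)
        block = D.d[np.ix_(ra, ra)]
        vals = block[np.triu_indices(len(a), k=1)]
    else:
        b = list(group_b)
        if not a or not b:
            raise DataError("groups must be non-empty")
        if set(a) & set(b):
            raise DataError("distinct groups must be disjoint")
        vals = D.d[np.ix_(D.index_of(a), D.index_of(b))].ravel()
    defined = vals[~np.isnan(vals)]
    if defined.size < vals.size:
        warnings.warn("undefined pairs excluded from group mean", stacklevel=2)
    if defined.size == 0:
        return float("nan")
    return float(defined.mean())


def clade_distance_table(
    D: DistanceMatrix, clade_members: Mapping[int, Sequence[str]]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Between-clade mean distances and their unweighted summary.

    Returns the clade × clade table (NaN diagonal) and a summary dict with
    the unweighted mean, min and max over clade pairs — the between-group
    mean convention of standard distance software.
    """
    clades = sorted(clade_members)
    if len(clades) < 2:
        raise DataError("need at least two clades")
    table = pd.DataFrame(np.nan, index=clades, columns=clades, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, g in enumerate(clades):
            for h in clades[i + 1:]:
                m = group_mean_distance(D, clade_members[g], clade_members[h])
                table.loc[g, h] = table.loc[h, g] = m
    pairs = table.values[np.triu_indices(len(clades), k=1)]
    defined = pairs[~np.isnan(pairs)]
    summary = {
        "mean": float(defined.mean()) if defined.size else float("nan"),
        "min": float(defined.min()) if defined.size else float("nan"),
        "max": float(defined.max()) if defined.size else float("nan"),
    }
    return table, summary


def validate_clade_divergence(
    D: DistanceMatrix,
    clade_members: Mapping[int, Sequence[str]],
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Check each clade's divergence from its nearest neighbour.

    A clade passes when its minimum between-clade mean distance exceeds
    ``threshold`` (default 1%, the delimitation rule for recognising clades).
    """
    table, _ = clade_distance_table(D, clade_members)
    rows = []
    for clade in table.index:
        others = table.loc[clade].drop(clade)
        nearest = others.idxmin()
        dist = float(others.min())
        rows.append(
            {
                "clade_id": clade,
                "nearest_clade": nearest,
                "distance": dist,
                "passes": bool(dist > threshold),
            }
        )
    return pd.DataFrame(rows)
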