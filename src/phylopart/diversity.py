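"""Per-group diversity statistics and sample-size standardization.

Statistics follow the standard population-genetics definitions:

* ``S`` — segregating sites: columns with at least two distinct resolved
  bases among the rows resolved there.
* ``pi`` — nucleotide diversity: mean pairwise p-distance (pairwise
  deletion), per site.
* ``h`` / ``Hd`` — haplotype count and diversity.  Haplotypes are
  equivalence classes by exact identity over the columns fully resolved in
  every row of the group (complete deletion within the group), and
  ``Hd = N/(N-1) * (1 - sum p_k^2)``.

Groups of unequal size are compared by rarefaction: each larger group is
subsampled (without replacement) to the smallest compared size ``s`` many
times and the statistics averaged, so every group is summarised at a common
sample size.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import distance_matrix, encode
from .errors import DataError
from .seq_io import Alignment


@dataclass
class DiversitySummary:
    group_id: str
    n: int
    sites_used: int
    S: float
    h: float
    Hd: float
    pi: float
    standardized: bool = False
    s: int | None = None
    n_resamples: int | None = None
    seed: int | None = None

    def as_row(self) -> dict:
        row = {
            "group": self.group_id,
            "N": self.n,
            "ns": self.sites_used,
            "S": self.S,
            "h": self.h,
            "Hd": self.Hd,
            "pi": self.pi,
            "pi_e3": self.pi * 1e3 if not np.isnan(self.pi) else np.nan,
            "standardized": self.standardized,
        }
        if self.standardized:
            row["s"] = self.s
        return row


def segregating_sites(alignment: Alignment) -> int:
    """Count columns with >=2 distinct resolved bases."""
    if alignment.n < 2:
        raise DataError("segregating sites needs at least two sequences")
    codes = encode(alignment.seqs)
    count = 0
    for col in codes.T:
        bases = np.unique(col[col < 4])
        if bases.size >= 2:
            count += 1
    return count


def nucleotide_diversity(alignment: Alignment) -> float:
    """Mean pairwise p-distance within the group (per site)."""
    D = distance_matrix(alignment)
    vals = D.d[np.triu_indices(alignment.n, k=1)]
    defined = vals[~np.isnan(vals)]
    if defined.size == 0:
        return float("nan")
    return float(defined.mean())


def haplotypes(alignment: Alignment) -> tuple[int, float, dict[str, int]]:
    """Haplotype count, diversity and the id → haplotype assignment.

    Columns carrying any unresolved symbol in the group are dropped first;
    identical remaining rows form one haplotype.  Returns ``(h, Hd,
    assignment)``; ``Hd`` is NaN when every column is unresolved.
    """
    if alignment.n < 2:
        raise DataError("haplotype diversity needs at least two sequences")
    codes = encode(alignment.seqs)
    keep = (codes < 4).all(axis=0)
    if not keep.any():
        return 0, float("nan"), {}
    rows = codes[:, keep]
    _, labels = np.unique(rows, axis=0, return_inverse=True)
    assignment = {sid: int(lab) for sid, lab in zip(alignment.ids, labels)}
    n = alignment.n
    freqs = np.bincount(labels) / n
    hd = (n / (n - 1)) * (1.0 - float((freqs**2).sum()))
    return int(freqs.size), hd, assignment


def group_summary(alignment: Alignment, group_id: str = "") -> DiversitySummary:
    """Raw (unstandardized) diversity summary for one group."""
    h, hd, _ = haplotypes(alignment)
    return DiversitySummary(
        group_id=group_id or alignment.locus_name,
        n=alignment.n,
        sites_used=alignment.length,
        S=float(segregating_sites(alignment)),
        h=float(h),
        Hd=hd,
        pi=nucleotide_diversity(alignment),
    )


def _group_rng(seed: int, group_id: str) -> np.random.Generator:
    # Per-group substream: adding or removing other groups never changes
    # this group's draws.
    return np.random.default_rng([seed, zlib.crc32(group_id.encode())])


def _resolved_sites_all(alignments: Mapping[str, Alignment]) -> int:
    """Complete-deletion site count over all compared groups pooled."""
    keep = None
    for aln in alignments.values():
        resolved = (encode(aln.seqs) < 4).all(axis=0)
        keep = resolved if keep is None else (keep & resolved)
    return int(keep.sum()) if keep is not None else 0


def standardized_diversity(
    groups: Mapping[str, Alignment],
    n_resamples: int = 100,
    seed: int = 0,
    s: int | None = None,
    replace: bool = False,
    exhaustive_limit: int = 0,
) -> dict[str, DiversitySummary]:
    """Rarefy each group to the smallest compared sample size.

    ``s`` defaults to the smallest group size among groups with at least two
    sequences (sizes 0 and 1 are ignored when choosing ``s``).  Groups at
    size ``s`` keep their raw values; larger groups are averaged over
    ``n_resamples`` random subsets of size ``s`` drawn without replacement
    (``replace=True`` switches to bootstrap draws).  With
    ``exhaustive_limit > 0``, groups whose subset count C(N, s) is at most
    that limit are averaged over *all* subsets instead of random ones.
    """
    sizes = {g: aln.n for g, aln in groups.items()}
    eligible = {g: n for g, n in sizes.items() if n >= 2}
    if not eligible:
        raise DataError("standardization needs a group with >=2 sequences")
    if s is None:
        s = min(eligible.values())
    if s < 2:
        raise DataError(f"resample size s={s} must be >=2")
    ns_pooled = _resolved_sites_all(
        {g: groups[g] for g in eligible}
    )
    out: dict[str, DiversitySummary] = {}
    for gid, aln in groups.items():
        if aln.n < 2 or aln.n < s:
            out[gid] = DiversitySummary(
                group_id=gid, n=aln.n, sites_used=aln.length,
                S=float("nan"), h=float("nan"), Hd=float("nan"),
                pi=float("nan"), standardized=True, s=s,
                n_resamples=0, seed=seed,
            )
            continue
        if aln.n == s:
            raw = group_summary(aln, gid)
            out[gid] = DiversitySummary(
                group_id=gid, n=aln.n, sites_used=ns_pooled,
                S=raw.S, h=raw.h, Hd=raw.Hd, pi=raw.pi,
                standardized=True, s=s, n_resamples=0, seed=seed,
            )
            continue
        if exhaustive_limit and comb(aln.n, s) <= exhaustive_limit:
            subsets = [list(c) for c in itertools.combinations(range(aln.n), s)]
        else:
            rng = _group_rng(seed, gid)
            if replace:
                subsets = [rng.integers(0, aln.n, size=s) for _ in range(n_resamples)]
            else:
                subsets = [
                    rng.choice(aln.n, size=s, replace=False)
                    for _ in range(n_resamples)
                ]
        stats = np.array(
            [
                _subset_stats(aln, idx)
                for idx in subsets
            ]
        )
        means = np.nanmean(stats, axis=0)
        out[gid] = DiversitySummary(
            group_id=gid, n=aln.n, sites_used=ns_pooled,
            S=float(means[0]), h=float(means[1]), Hd=float(means[2]),
            pi=float(means[3]), standardized=True, s=s,
            n_resamples=len(subsets), seed=seed,
        )
    return out


def _subset_stats(aln: Alignment, idx) -> tuple[float, float, float, float]:
    sub = Alignment(
        locus_name=aln.locus_name,
        ids=[aln.ids[i] for i in idx],
        seqs=aln.seqs[np.asarray(idx)],
    )
    h, hd, _ = haplotypes(sub)
    return (
        float(segregating_sites(sub)),
        float(h),
        hd,
        nucleotide_diversity(sub),
    )


def diversity_report(
    groups_by_locus: Mapping[str, Mapping[str, Alignment]],
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw + standardized summary rows per locus × group.

    ``s`` is chosen per locus across that locus's compared groups, so
    standardized rows are comparable within a locus.  π is additionally
    reported ×10³.
    """
    rows = []
    for locus, groups in groups_by_locus.items():
        std = standardized_diversity(groups, n_resamples=n_resamples, seed=seed)
        for gid, aln in groups.items():
            if aln.n >= 2:
                raw = group_summary(aln, gid).as_row()
            else:
                raw = {
                    "group": gid, "N": aln.n, "ns": aln.length,
                    "S": np.nan, "h": np.nan, "Hd": np.nan,
                    "pi": np.nan, "pi_e3": np.nan, "standardized": False,
                }
            raw["locus"] = locus
            rows.append(raw)
            srow = std[gid].as_row()
            srow["locus"] = locus
            rows.append(srow)
    cols = ["locus", "group", "standardized", "N", "ns", "S", "h", "Hd",
            "pi", "pi_e3", "s"]
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan
    return frame[cols]
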