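"""Permutation inference on distance partitions.

Three related procedures, all operating on a p-distance matrix and a
partition of the sequences:

* **AMOVA Φ_ST** — two-level analysis of molecular variance on squared
  distances, partitioning variance among vs within groups, with a
  label-permutation significance test.
* **D_bc vs D_wc** — pooled mean between-clade distance minus pooled mean
  within-clade distance, with a permutation null built by shuffling
  individuals among clades (clade sizes fixed).
* **Northern-origin tests** — for a "northern" locality, its mean distance
  D_i to a reference set of southern localities is compared against the
  between-clade and within-clade levels: a significant D_i − D_wc together
  with a non-significant D_bc − D_i places the locality at between-clade
  divergence, i.e. an independently persisting (in-situ) lineage rather
  than a postglacial offshoot of the southern pool.

p-values use the (exceedances + 1)/(n_perm + 1) convention by default, so
the smallest reportable value at 1000 permutations is 0.001; ties count as
exceedances.  All tests are reproducible from an integer seed.  Sequences
can be tied into multi-row exchangeable units (e.g. the two phased
haplotypes of a diploid individual) so that units, not rows, are permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import ConfigError, DataError

__all__ = [
    "PartitionScheme",
    "PermutationResult",
    "FstResult",
    "amova_phist",
    "fst_permutation_test",
    "bc_wc_statistics",
    "test_bc_vs_wc",
    "northern_origin_test",
    "run_origin_battery",
    "scheme_from_tables",
    "classify_origin",
    "classify_battery",
]


@dataclass
class PermutationResult:
    statistic: str
    observed: dict[str, float]
    n_perm: int
    p_values: dict[str, float]
    seed: int | None
    null_summary: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class FstResult:
    phi_st: float
    sigma_among: float
    sigma_within: float
    n_perm: int = 0
    p_value: float = float("nan")
    seed: int | None = None


@dataclass
class PartitionScheme:
    """Locality/clade/region structure consumed by the origin tests."""

    locality_of: dict[str, int]
    clade_of_locality: dict[int, int]
    northern: frozenset[int]
    southern_sets: dict[str, frozenset[int]]
    individual_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        all_southern = self.southern_sets.get("all_southern", frozenset())
        if self.northern & all_southern:
            raise ConfigError("northern and southern locality sets overlap")
        for name, locs in self.southern_sets.items():
            if name != "all_southern" and not locs <= all_southern:
                raise ConfigError(
                    f"contiguous set {name!r} is not a subset of all_southern"
                )

    def clade_of_id(self, sid: str) -> int | None:
        loc = self.locality_of.get(sid)
        return self.clade_of_locality.get(loc) if loc is not None else None


def scheme_from_tables(
    sample_table: pd.DataFrame,
    region_config: Mapping,
    individual_of: Mapping[str, str] | None = None,
) -> PartitionScheme:
    """Build a scheme from a sample table plus a region config.

    The region config supplies ``northern`` and ``southern`` locality lists
    and optional ``contiguous_blocks``; clade membership comes from the
    sample table's locality → clade mapping.
    """
    locality_of = dict(
        zip(sample_table["specimen_id"], sample_table["locality_code"].astype(int))
    )
    clade_rows = sample_table.dropna(subset=["clade_id"])
    clade_of_locality = {
        int(loc): int(cl)
        for loc, cl in zip(clade_rows["locality_code"], clade_rows["clade_id"])
    }
    southern = frozenset(int(x) for x in region_config["southern"])
    sets: dict[str, frozenset[int]] = {"all_southern": southern}
    for block in region_config.get("contiguous_blocks", []):
        for name, locs in block.get("southern_sets", {}).items():
            sets[f"contig_{name}"] = frozenset(int(x) for x in locs)
    return PartitionScheme(
        locality_of=locality_of,
        clade_of_locality=clade_of_locality,
        northern=frozenset(int(x) for x in region_config["northern"]),
        southern_sets=sets,
        individual_of=dict(individual_of) if individual_of else None,
    )


# ---------------------------------------------------------------------------
# internal helpers


def _p_value(exceed: int, n_perm: int, mode: str) -> float:
    if mode == "plus_one":
        return (exceed + 1) / (n_perm + 1)
    if mode == "raw":
        return exceed / n_perm
    raise ConfigError(f"unknown p-value mode {mode!r}")


def _group_rows(labels: np.ndarray) -> list[np.ndarray]:
    return [np.where(labels == g)[0] for g in np.unique(labels) if g >= 0]


def _pooled_bc_wc(d: np.ndarray, rows_per_group: list[np.ndarray]) -> tuple[float, float]:
    """Pooled between/within means over all labelled rows; NaN-pair safe."""
    labelled = np.concatenate(rows_per_group) if rows_per_group else np.array([], int)
    sub = d[np.ix_(labelled, labelled)]
    defined = ~np.isnan(sub)
    np.fill_diagonal(defined, False)
    total_sum = np.nansum(np.where(defined, sub, 0.0)) / 2.0
    total_cnt = defined.sum() / 2.0
    w_sum = w_cnt = 0.0
    for rows in rows_per_group:
        if rows.size < 2:
            continue
        blk = d[np.ix_(rows, rows)]
        dfn = ~np.isnan(blk)
        np.fill_diagonal(dfn, False)
        w_sum += np.nansum(np.where(dfn, blk, 0.0)) / 2.0
        w_cnt += dfn.sum() / 2.0
    b_sum, b_cnt = total_sum - w_sum, total_cnt - w_cnt
    d_bc = b_sum / b_cnt if b_cnt > 0 else float("nan")
    d_wc = w_sum / w_cnt if w_cnt > 0 else float("nan")
    return d_bc, d_wc


def _clade_pair_mean_bc(d: np.ndarray, rows_per_group: list[np.ndarray]) -> float:
    """Alternative D_bc: unweighted mean of clade-pair mean distances."""
    means = []
    for i in range(len(rows_per_group)):
        for j in range(i + 1, len(rows_per_group)):
            blk = d[np.ix_(rows_per_group[i], rows_per_group[j])]
            if np.isfinite(blk).any():
                means.append(np.nanmean(blk))
    return float(np.mean(means)) if means else float("nan")


def _units(ids: Sequence[str], individual_of: Mapping[str, str] | None) -> list[np.ndarray]:
    """Row-index groups that move together under permutation."""
    if not individual_of:
        return [np.array([i]) for i in range(len(ids))]
    by_ind: dict[str, list[int]] = {}
    for i, sid in enumerate(ids):
        by_ind.setdefault(individual_of.get(sid, sid), []).append(i)
    return [np.array(v) for v in by_ind.values()]


def _null_summary(draws: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(draws)),
        "q05": float(np.quantile(draws, 0.05)),
        "q50": float(np.quantile(draws, 0.50)),
        "q95": float(np.quantile(draws, 0.95)),
    }


# ---------------------------------------------------------------------------
# AMOVA


def amova_phist(
    D: DistanceMatrix, groups: Mapping[str, int | str]
) -> FstResult:
    """Two-level AMOVA Φ_ST from squared pairwise distances.

    ``groups`` maps sequence id → group label; groups with fewer than two
    members are dropped with a warning.  Undefined (NaN) distances are
    excluded from the sums of squares.
    """
    by_group: dict = {}
    for sid, g in groups.items():
        by_group.setdefault(g, []).append(sid)
    kept = {g: m for g, m in by_group.items() if len(m) >= 2}
    if len(kept) < len(by_group):
        warnings.warn(
            f"dropped {len(by_group) - len(kept)} group(s) with <2 members",
            stacklevel=2,
        )
    if len(kept) < 2:
        raise DataError("AMOVA needs >=2 groups with >=2 members")
    ids = [sid for m in kept.values() for sid in m]
    labels = np.concatenate(
        [np.full(len(m), k) for k, m in enumerate(kept.values())]
    )
    sub = D.submatrix(ids)
    phi, s_a, s_w = _phist_from_labels(sub.d**2, labels)
    return FstResult(phi_st=phi, sigma_among=s_a, sigma_within=s_w)


def _phist_from_labels(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = len(labels)
    rows_per_group = _group_rows(labels)
    g = len(rows_per_group)
    iu = np.triu_indices(n, k=1)
    ss_total = np.nansum(d2[iu]) / n
    ss_within = 0.0
    for rows in rows_per_group:
        blk = d2[np.ix_(rows, rows)]
        ss_within += np.nansum(blk[np.triu_indices(rows.size, k=1)]) / rows.size
    ss_among = ss_total - ss_within
    sizes = np.array([r.size for r in rows_per_group])
    sigma_w = ss_within / (n - g)
    n_bar = (n - (sizes**2).sum() / n) / (g - 1)
    sigma_a = (ss_among / (g - 1) - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else float("nan")
    return float(phi), float(sigma_a), float(sigma_w)


def fst_permutation_test(
    D: DistanceMatrix,
    groups: Mapping[str, int | str],
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "plus_one",
    individual_of: Mapping[str, str] | None = None,
) -> FstResult:
    """Φ_ST with permutation significance.

    The null shuffles individuals among groups holding group sizes fixed;
    p is the proportion of permuted Φ_ST at least as large as observed.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    point = amova_phist(D, groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        by_group: dict = {}
        for sid, g in groups.items():
            by_group.setdefault(g, []).append(sid)
        kept = {g: m for g, m in by_group.items() if len(m) >= 2}
        ids = [sid for m in kept.values() for sid in m]
        labels = np.concatenate(
            [np.full(len(m), k) for k, m in enumerate(kept.values())]
        )
        d2 = D.submatrix(ids).d ** 2
        units = _units(ids, individual_of)
        rng = np.random.default_rng(seed)
        exceed = 0
        draws = np.empty(n_perm)
        for k in range(n_perm):
            perm_labels = _permute_unit_labels(labels, units, rng)
            phi, _, _ = _phist_from_labels(d2, perm_labels)
            draws[k] = phi
            if phi >= point.phi_st:
                exceed += 1
    return FstResult(
        phi_st=point.phi_st,
        sigma_among=point.sigma_among,
        sigma_within=point.sigma_within,
        n_perm=n_perm,
        p_value=_p_value(exceed, n_perm, p_mode),
        seed=seed,
    )


def _permute_unit_labels(
    labels: np.ndarray, units: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Shuffle unit → label-slot assignment; rows of a unit move together."""
    unit_labels = np.array([labels[u[0]] for u in units])
    perm = rng.permutation(len(units))
    out = np.empty_like(labels)
    for slot_label, unit_idx in zip(unit_labels, perm):
        out[units[unit_idx]] = slot_label
    return out


# ---------------------------------------------------------------------------
# D_bc vs D_wc


def bc_wc_statistics(
    D: DistanceMatrix,
    clades: Mapping[str, int],
    bc_mode: str = "pooled",
) -> tuple[float, float]:
    """Pooled mean between-clade and within-clade distances.

    ``clades`` maps sequence id → clade label.  ``bc_mode="pair_means"``
    instead averages the clade-pair mean distances (unweighted).
    """
    ids = list(clades)
    if len(set(clades.values())) < 2:
        sub = D.submatrix(ids)
        rows = _group_rows(np.zeros(len(ids), dtype=int))
        _, d_wc = _pooled_bc_wc(sub.d, rows)
        return float("nan"), d_wc
    sub = D.submatrix(ids)
    uniq = {c: k for k, c in enumerate(sorted(set(clades.values())))}
    labels = np.array([uniq[clades[i]] for i in ids])
    rows = _group_rows(labels)
    d_bc, d_wc = _pooled_bc_wc(sub.d, rows)
    if bc_mode == "pair_means":
        d_bc = _clade_pair_mean_bc(sub.d, rows)
    elif bc_mode != "pooled":
        raise ConfigError(f"unknown bc_mode {bc_mode!r}")
    return d_bc, d_wc


def test_bc_vs_wc(
    D: DistanceMatrix,
    clades: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "plus_one",
    individual_of: Mapping[str, str] | None = None,
) -> PermutationResult:
    """One-sided permutation test of D_bc > D_wc.

    Individuals are shuffled among clades (clade sizes fixed) to build the
    null distribution of T = D_bc − D_wc; p is the proportion of permuted T
    at least as large as observed (ties count).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    ids = list(clades)
    uniq = sorted(set(clades.values()))
    if len(uniq) < 2:
        raise DataError("bc-vs-wc test needs >=2 clades")
    lookup = {c: k for k, c in enumerate(uniq)}
    labels = np.array([lookup[clades[i]] for i in ids])
    sizes = np.bincount(labels)
    if (sizes >= 2).sum() == 0:
        raise DataError("no clade has >=2 members; D_wc undefined")
    sub = D.submatrix(ids)
    rows = _group_rows(labels)
    d_bc, d_wc = _pooled_bc_wc(sub.d, rows)
    t_obs = d_bc - d_wc
    units = _units(ids, individual_of)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    exceed = 0
    for k in range(n_perm):
        perm_labels = _permute_unit_labels(labels, units, rng)
        pb, pw = _pooled_bc_wc(sub.d, _group_rows(perm_labels))
        draws[k] = pb - pw
        if draws[k] >= t_obs:
            exceed += 1
    return PermutationResult(
        statistic="D_bc - D_wc",
        observed={"D_bc": d_bc, "D_wc": d_wc, "T": t_obs},
        n_perm=n_perm,
        p_values={"p": _p_value(exceed, n_perm, p_mode)},
        seed=seed,
        null_summary={"T": _null_summary(draws)},
    )


# ---------------------------------------------------------------------------
# northern-locality origin tests


def northern_origin_test(
    D: DistanceMatrix,
    scheme: PartitionScheme,
    northern_locality: int,
    southern_set: Iterable[int],
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "plus_one",
) -> PermutationResult:
    """Test whether a northern locality sits at between- or within-clade divergence.

    D_i is the mean distance between the northern locality's sequences and
    the reference southern set's sequences.  Each permutation reassigns
    individuals to locality slots (locality sizes fixed; clade labels follow
    localities) and recomputes D_i, D_bc and D_wc.  Two one-sided p-values
    are returned: ``p_bc`` for D_bc − D_i (is D_i *below* the between-clade
    level?) and ``p_wc`` for D_i − D_wc (is D_i *above* the within-clade
    level?).
    """
    southern_set = frozenset(int(x) for x in southern_set)
    ids = [sid for sid, loc in scheme.locality_of.items() if sid in set(D.ids)]
    if not ids:
        raise DataError("no sequences overlap the scheme")
    locs = np.array([scheme.locality_of[i] for i in ids])
    north_rows = np.where(locs == northern_locality)[0]
    south_rows = np.where(np.isin(locs, list(southern_set)))[0]
    if north_rows.size < 1:
        raise DataError(f"northern locality {northern_locality} has no sequences")
    if south_rows.size < 2:
        raise DataError("southern reference set needs >=2 sequences")
    sub = D.submatrix(ids)
    clade_labels = np.array(
        [scheme.clade_of_locality.get(l, -1) for l in locs]
    )
    lookup = {c: k for k, c in enumerate(sorted(set(clade_labels[clade_labels >= 0])))}
    labels = np.array([lookup.get(c, -1) for c in clade_labels])

    def stats(loc_assign: np.ndarray) -> tuple[float, float, float]:
        nr = np.where(loc_assign == northern_locality)[0]
        sr = np.where(np.isin(loc_assign, list(southern_set)))[0]
        blk = sub.d[np.ix_(nr, sr)]
        d_i = float(np.nanmean(blk)) if np.isfinite(blk).any() else float("nan")
        cl = np.array(
            [lookup.get(scheme.clade_of_locality.get(l, -1), -1) for l in loc_assign]
        )
        d_bc, d_wc = _pooled_bc_wc(sub.d, _group_rows(cl))
        return d_i, d_bc, d_wc

    d_i, d_bc, d_wc = stats(locs)
    obs_bc, obs_wc = d_bc - d_i, d_i - d_wc
    units = _units(ids, scheme.individual_of)
    rng = np.random.default_rng(seed)
    exc_bc = exc_wc = 0
    null_bc = np.empty(n_perm)
    null_wc = np.empty(n_perm)
    for k in range(n_perm):
        perm_locs = _permute_unit_labels(locs, units, rng)
        pi_, pb, pw = stats(perm_locs)
        null_bc[k] = pb - pi_
        null_wc[k] = pi_ - pw
        if null_bc[k] >= obs_bc:
            exc_bc += 1
        if null_wc[k] >= obs_wc:
            exc_wc += 1
    return PermutationResult(
        statistic="northern-origin",
        observed={"D_i": d_i, "D_bc": d_bc, "D_wc": d_wc},
        n_perm=n_perm,
        p_values={
            "p_bc": _p_value(exc_bc, n_perm, p_mode),
            "p_wc": _p_value(exc_wc, n_perm, p_mode),
        },
        seed=seed,
        null_summary={
            "D_bc - D_i": _null_summary(null_bc),
            "D_i - D_wc": _null_summary(null_wc),
        },
    )


def classify_origin(result: PermutationResult, alpha: float = 0.05) -> str:
    """Interpret a northern-origin test.

    ``in_situ``: D_i is at the between-clade level (D_i − D_wc significant,
    D_bc − D_i not) — an independently persisting northern lineage.
    ``southern_origin``: D_i is not above the within-clade level — the
    locality looks like an offshoot of the southern pool.  ``ambiguous``
    otherwise.
    """
    p_bc = result.p_values["p_bc"]
    p_wc = result.p_values["p_wc"]
    if p_wc <= alpha and p_bc > alpha:
        return "in_situ"
    if p_wc > alpha:
        return "southern_origin"
    return "ambiguous"


def classify_battery(battery: pd.DataFrame, alpha: float = 0.05) -> dict[int, str]:
    """Per-locality scenario call from a full origin-test battery.

    A northern locality is called ``southern_origin`` when *any* reference
    set (all-southern or a contiguous refugium) leaves D_i at the
    within-clade level (p_wc non-significant): its sequences are
    exchangeable with that southern pool.  It is called ``in_situ`` when
    D_i is significantly above the within-clade level against every
    reference set — the locality is not an offshoot of any southern
    region.  The between-level comparison (p_bc) is reported per row as a
    diagnostic but does not drive the call: when lineage divergences vary
    severalfold, an independent northern lineage can sit legitimately
    below the pooled between-clade mean.
    """
    out: dict[int, str] = {}
    for loc, grp in battery.groupby("locality"):
        p_wc = grp["p_wc"].dropna()
        if not len(p_wc):
            out[int(loc)] = "undetermined"
        elif (p_wc > alpha).any():
            out[int(loc)] = "southern_origin"
        else:
            out[int(loc)] = "in_situ"
    return out


def run_origin_battery(
    D: DistanceMatrix,
    scheme: PartitionScheme,
    n_perm: int = 1000,
    seed: int = 0,
    region_config: Mapping | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (northern locality × reference set) origin tests.

    Every sampled northern locality is tested against the all-southern set
    and against each contiguous set its block defines (localities between
    two refugia get both).  Seeds are derived per row so the battery is
    reproducible yet rows are independent.
    """
    ids_present = set(D.ids)
    locs_present = {
        scheme.locality_of[i] for i in scheme.locality_of if i in ids_present
    }
    contiguous_of: dict[int, list[str]] = {}
    if region_config:
        for block in region_config.get("contiguous_blocks", []):
            for loc in block["northern"]:
                for name in block.get("southern_sets", {}):
                    contiguous_of.setdefault(int(loc), []).append(f"contig_{name}")
    rows = []
    row_seed = seed
    for loc in sorted(scheme.northern & locs_present):
        set_names = ["all_southern"] + contiguous_of.get(loc, [])
        for name in set_names:
            ref = scheme.southern_sets.get(name)
            if ref is None:
                continue
            row_seed += 1
            try:
                res = northern_origin_test(
                    D, scheme, loc, ref, n_perm=n_perm, seed=row_seed
                )
            except DataError as exc:
                rows.append(
                    {"locality": loc, "reference_set": name, "error": str(exc)}
                )
                continue
            rows.append(
                {
                    "locality": loc,
                    "reference_set": name,
                    "D_i": res.observed["D_i"],
                    "D_bc": res.observed["D_bc"],
                    "D_wc": res.observed["D_wc"],
                    "p_bc": res.p_values["p_bc"],
                    "p_wc": res.p_values["p_wc"],
                    "classification": classify_origin(res, alpha=alpha),
                    "n_perm": n_perm,
                    "seed": row_seed,
                }
            )
    return pd.DataFrame(rows)
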