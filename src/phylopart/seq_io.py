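"""Alignment and sample-metadata I/O.

Sequences are held as a fixed-width byte matrix of upper-case IUPAC symbols;
`-` marks alignment gaps and ambiguity codes/`N` are carried through (the
distance layer decides what counts as resolved).  Sample metadata is a pandas
DataFrame with one row per specimen, linking it to a locality, a mitochondrial
clade and a biogeographic region (northern / southern / unassigned).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DataError, MetadataError, ParseError

# A,C,G,T plus IUPAC ambiguity codes, N and the gap symbol.
IUPAC_SYMBOLS = frozenset(b"ACGTRYSWKMBDHVN-")

SAMPLE_COLUMNS = [
    "specimen_id",
    "locality_code",
    "locality_name",
    "lat",
    "lon",
    "clade_id",
    "region",
]

REGIONS = ("northern", "southern", "unassigned")


@dataclass
class Alignment:
    """Equal-length nucleotide sequences for one locus.

    Attributes
    ----------
    locus_name : str
        Label for the locus (e.g. ``"cytb"``).
    ids : list of str
        Unique sequence identifiers, input order preserved.
    seqs : numpy.ndarray
        ``(N, L)`` array of dtype ``S1``, upper case.
    locus_ranges : dict
        For concatenated alignments, half-open column ranges per locus.
    """

    locus_name: str
    ids: list[str]
    seqs: np.ndarray
    locus_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2 or self.seqs.shape[1] == 0:
            raise AlignmentError(
                f"{self.locus_name}: alignment must be a non-empty 2-D matrix"
            )
        if len(self.ids) != self.seqs.shape[0]:
            raise AlignmentError(
                f"{self.locus_name}: {len(self.ids)} ids for "
                f"{self.seqs.shape[0]} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise MetadataError(f"{self.locus_name}: duplicate ids {dupes}")
        bad = ~np.isin(self.seqs, [bytes([c]) for c in IUPAC_SYMBOLS])
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(
                f"{self.locus_name}: illegal symbol "
                f"{self.seqs[r, c].decode()!r} in sequence {self.ids[r]!r} "
                f"at column {c}"
            )
        if not self.locus_ranges:
            self.locus_ranges = {self.locus_name: (0, self.seqs.shape[1])}

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @classmethod
    def from_records(
        cls, records: Mapping[str, str] | Iterable[tuple[str, str]],
        locus_name: str = "locus",
    ) -> "Alignment":
        """Build an alignment from ``(id, sequence)`` pairs.

        Parsing is case-insensitive and maps RNA ``U`` to ``T``.
        """
        pairs = list(records.items()) if isinstance(records, Mapping) else list(records)
        if not pairs:
            raise DataError(f"{locus_name}: no sequences")
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{locus_name}: ragged sequence lengths {sorted(lengths)}"
            )
        ids = [i for i, _ in pairs]
        mat = np.array(
            [list(s.upper().replace("U", "T")) for _, s in pairs], dtype="S1"
        )
        return cls(locus_name=locus_name, ids=ids, seqs=mat)

    def to_dict(self) -> dict[str, str]:
        return {
            i: self.seqs[k].tobytes().decode()
            for k, i in enumerate(self.ids)
        }

    def subset(
        self,
        ids: Sequence[str] | None = None,
        localities: Iterable[int] | None = None,
        clades: Iterable[int] | None = None,
        sample_table: pd.DataFrame | None = None,
    ) -> "Alignment":
        """Row-subset by explicit ids, or by locality/clade via a sample table."""
        if ids is None:
            if sample_table is None:
                raise DataError("subset by locality/clade requires a sample table")
            tab = sample_table
            if localities is not None:
                tab = tab[tab["locality_code"].isin(set(localities))]
            if clades is not None:
                tab = tab[tab["clade_id"].isin(set(clades))]
            wanted = set(tab["specimen_id"])
            ids = [i for i in self.ids if i in wanted]
        else:
            missing = [i for i in ids if i not in set(self.ids)]
            if missing:
                raise KeyError(f"{self.locus_name}: unknown ids {missing}")
        if len(ids) == 0:
            raise DataError(f"{self.locus_name}: subset selects no sequences")
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return Alignment(
            locus_name=self.locus_name,
            ids=list(ids),
            seqs=self.seqs[rows],
            locus_ranges=dict(self.locus_ranges),
        )


def read_fasta(path: str | Path, locus_name: str | None = None) -> Alignment:
    """Read an aligned FASTA file.

    The sequence id is the header token up to the first whitespace.  All
    records must have the same length; symbols are validated against the
    IUPAC nucleotide alphabet (plus ``N`` and ``-``).
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return Alignment.from_records(records, locus_name=locus_name or path.stem)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.to_dict().items()
    ]
    SeqIO.write(recs, str(Path(path)), "fasta")


def concat_loci(alignments: Sequence[Alignment], mode: str = "intersection") -> Alignment:
    """Concatenate loci, keeping specimens present in *all* input loci.

    The combined alignment records per-locus column ranges (0-based,
    half-open).  Specimens missing any locus are dropped rather than padded.
    """
    if len(alignments) < 2:
        raise DataError("concat_loci needs at least two alignments")
    if mode != "intersection":
        raise DataError(f"unsupported concat mode {mode!r}")
    shared = set(alignments[0].ids)
    for aln in alignments[1:]:
        shared &= set(aln.ids)
    if not shared:
        raise DataError("no specimens shared across all loci")
    # Preserve the first alignment's order for the shared ids.
    ids = [i for i in alignments[0].ids if i in shared]
    blocks, ranges, offset = [], {}, 0
    for aln in alignments:
        index = {i: k for k, i in enumerate(aln.ids)}
        blocks.append(aln.seqs[[index[i] for i in ids]])
        ranges[aln.locus_name] = (offset, offset + aln.length)
        offset += aln.length
    name = "+".join(a.locus_name for a in alignments)
    return Alignment(
        locus_name=name, ids=ids, seqs=np.hstack(blocks), locus_ranges=ranges
    )


def load_sample_table(path: str | Path) -> pd.DataFrame:
    """Load the specimen metadata TSV and validate its invariants.

    Required columns: specimen_id, locality_code, locality_name, lat, lon,
    clade_id, region.  ``clade_id`` may be empty (unassigned); ``region``
    defaults to ``unassigned`` where empty or unrecognised.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in tab.columns]
    if missing:
        raise MetadataError(f"{path}: missing columns {missing}")
    return validate_sample_table(tab)


def validate_sample_table(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab.copy()
    if tab["specimen_id"].duplicated().any():
        dupes = sorted(tab.loc[tab["specimen_id"].duplicated(), "specimen_id"])
        raise MetadataError(f"duplicate specimen ids {dupes}")
    tab["clade_id"] = pd.to_numeric(tab["clade_id"], errors="coerce").astype("Int64")
    tab["region"] = (
        tab["region"].fillna("unassigned").where(
            tab["region"].isin(REGIONS), "unassigned"
        )
    )
    if len(tab):
        per_loc = tab.groupby("locality_code").agg(
            clades=("clade_id", lambda s: s.dropna().nunique()),
            regions=("region", "nunique"),
        )
        bad = per_loc[(per_loc["clades"] > 1) | (per_loc["regions"] > 1)]
        if len(bad):
            raise MetadataError(
                f"localities mapped to >1 clade or region: {list(bad.index)}"
            )
    return tab


def default_sample_table() -> pd.DataFrame:
    """The study's shipped specimen metadata (outgroups excluded)."""
    with importlib.resources.files("phylopart.data").joinpath(
        "specimens.tsv"
    ).open() as fh:
        tab = pd.read_csv(fh, sep="\t", dtype={"specimen_id": str})
    tab = tab[tab["outgroup"] == 0].drop(columns="outgroup")
    return validate_sample_table(tab)


def default_region_config() -> dict:
    """Northern/southern locality lists and contiguous reference sets."""
    with importlib.resources.files("phylopart.data").joinpath(
        "regions.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def clade_map(sample_table: pd.DataFrame, min_members: int = 2) -> pd.DataFrame:
    """Summarise clades: member localities, specimen counts, small-clade flag.

    Clades with fewer than ``min_members`` specimens are flagged; variance
    analyses exclude them.
    """
    tab = sample_table.dropna(subset=["clade_id"])
    rows = []
    for clade, grp in tab.groupby("clade_id"):
        rows.append(
            {
                "clade_id": int(clade),
                "localities": sorted(grp["locality_code"].unique()),
                "n_specimens": len(grp),
                "flagged_small": len(grp) < min_members,
            }
        )
    return pd.DataFrame(rows)
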