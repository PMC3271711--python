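"""Data model and I/O for OTU count tables, sample metadata, taxonomy, and trees.

The in-memory currency of the package is :class:`CountTable`, an integer
OTU x sample abundance matrix backed by a :class:`pandas.DataFrame`, together
with per-sample metadata (:class:`SampleRecord`), an OTU -> ranked-lineage
taxonomy (:class:`TaxonomyMap`), and a rooted phylogeny over OTU ids
(parsed with scikit-bio's newick reader).

File formats are the classic tab-delimited ones used by early microbial
ecology pipelines: an OTU table whose header starts with ``#OTU ID`` and may
carry a trailing taxonomy column, and a mapping file whose header starts with
``#SampleID``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: taxonomic ranks used throughout, ordered from coarse to fine
RANKS = ("phylum", "class", "order", "family", "genus")

#: sentinel for a rank that could not be assigned
UNCLASSIFIED = "unclassified"

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class CountTable:
    """Integer OTU x sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by OTU id, columns by sample id, non-negative integer
        read counts.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integers")
            data = data.astype(np.int64)
        if values.size and (data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self._df = data.astype(np.int64) if values.size else data.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_sums(self) -> pd.Series:
        """Sequencing depth (column sum) per sample."""
        return self._df.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean OTU x sample occupancy (count > 0)."""
        return self._df > 0

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountTable(self._df.loc[:, list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        missing = [o for o in otu_ids if o not in self._df.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return CountTable(self._df.loc[list(otu_ids)])

    def drop_empty_otus(self) -> "CountTable":
        return CountTable(self._df.loc[self._df.sum(axis=1) > 0])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        n_otu, n_samp = self.shape
        return f"CountTable({n_otu} OTUs x {n_samp} samples)"


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sample: who, where on the body, and when."""

    sample_id: str
    subject: str
    habitat: str
    day: int | None

    def matches(self, subject: str | None, habitat: str | None) -> bool:
        """Predicate used by sample-type selectors; ``None`` or ``"*"`` match all."""
        ok_s = subject in (None, "*") or self.subject == subject
        ok_h = habitat in (None, "*") or self.habitat == habitat
        return ok_s and ok_h


class TaxonomyMap:
    """OTU id -> ranked lineage (phylum..genus, 5 ranks, padded with a sentinel)."""

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for otu_id, lineage in lineages.items():
            self._lineages[otu_id] = normalize_lineage(lineage)

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return self._lineages[otu_id]

    def at_rank(self, otu_id: str, rank: str) -> str:
        """Taxon name of ``otu_id`` at ``rank`` (one of :data:`RANKS`)."""
        return self._lineages[otu_id][_rank_index(rank)]

    def prefix(self, otu_id: str, rank: str) -> tuple[str, ...]:
        """Lineage truncated at ``rank`` inclusive; groups OTUs for collapsing."""
        return self._lineages[otu_id][: _rank_index(rank) + 1]

    def items(self):
        return self._lineages.items()


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def normalize_lineage(lineage: Sequence[str]) -> tuple[str, ...]:
    """Strip Greengenes-style rank prefixes, drop a leading kingdom, pad to 5 ranks."""
    parts = [p.strip() for p in lineage]
    cleaned = []
    for p in parts:
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        cleaned.append(p if p else UNCLASSIFIED)
    # a 6-part lineage starting at kingdom/domain: drop the kingdom
    if len(cleaned) > len(RANKS):
        cleaned = cleaned[1 : len(RANKS) + 1]
    while len(cleaned) < len(RANKS):
        cleaned.append(UNCLASSIFIED)
    return tuple(cleaned)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TAXONOMY_HEADERS = {"consensus lineage", "taxonomy"}


def read_classic_table(path) -> tuple[CountTable, TaxonomyMap | None]:
    """Read a classic tab-delimited OTU table.

    The first non-comment header line must begin with ``#OTU ID``. A trailing
    ``Consensus Lineage`` or ``taxonomy`` column, when present, is split on
    ``;`` into ranks and returned as a :class:`TaxonomyMap` (otherwise None).
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header_idx = next(
        (i for i, ln in enumerate(lines) if ln.startswith("#OTU ID")), None
    )
    if header_idx is None:
        raise ValueError(f"{path}: no '#OTU ID' header line found")
    header = lines[header_idx].split("\t")
    has_tax = header[-1].strip().lower() in _TAXONOMY_HEADERS
    sample_ids = header[1 : -1 if has_tax else None]

    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineages: dict[str, list[str]] = {}
    for ln in lines[header_idx + 1 :]:
        fields = ln.split("\t")
        otu_id = fields[0]
        count_fields = fields[1 : 1 + len(sample_ids)]
        if len(count_fields) != len(sample_ids):
            raise ValueError(f"{path}: row {otu_id!r} has {len(count_fields)} "
                             f"counts, expected {len(sample_ids)}")
        row = []
        for sample_id, tok in zip(sample_ids, count_fields):
            try:
                val = int(tok)
            except ValueError:
                # classic tables sometimes carry float-formatted integers
                fval = float(tok)
                if fval != int(fval):
                    raise ValueError(
                        f"{path}: non-integer count {tok!r} at OTU {otu_id!r}, "
                        f"sample {sample_id!r}"
                    ) from None
                val = int(fval)
            row.append(val)
        otu_ids.append(otu_id)
        rows.append(row)
        if has_tax:
            lineages[otu_id] = fields[-1].split(";")

    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError(f"{path}: duplicate OTU ids")
    df = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=np.int64)
    table = CountTable(df)
    return table, (TaxonomyMap(lineages) if has_tax else None)


def write_classic_table(path, table: CountTable,
                        taxonomy: TaxonomyMap | None = None) -> None:
    """Write a classic OTU table (UTF-8, tab-separated, LF line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for otu_id, row in table.df.iterrows():
            fields = [str(otu_id), *(str(int(v)) for v in row)]
            if taxonomy is not None:
                fields.append("; ".join(taxonomy.lineage(otu_id)))
            fh.write("\t".join(fields) + "\n")


_REQUIRED_MAPPING_COLS = ("SampleID", "Subject", "BodySite", "Day")


def read_mapping(path) -> list[SampleRecord]:
    """Read a tab-delimited mapping file with a ``#SampleID`` header line."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].lstrip("#").startswith("SampleID"):
        raise ValueError(f"{path}: mapping file must start with '#SampleID' header")
    header = [c.lstrip("#") for c in lines[0].split("\t")]
    missing = [c for c in _REQUIRED_MAPPING_COLS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    idx = {c: header.index(c) for c in _REQUIRED_MAPPING_COLS}
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        fields = ln.split("\t")
        sid = fields[idx["SampleID"]]
        if sid in seen:
            raise ValueError(f"{path}: duplicate SampleID {sid!r}")
        seen.add(sid)
        day_tok = fields[idx["Day"]].strip()
        day = None if day_tok in ("", "NA", "None") else int(day_tok)
        records.append(
            SampleRecord(sid, fields[idx["Subject"]], fields[idx["BodySite"]], day)
        )
    return records


def write_mapping(path, records: Iterable[SampleRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#SampleID\tSubject\tBodySite\tDay\n")
        for r in records:
            day = "NA" if r.day is None else str(r.day)
            fh.write(f"{r.sample_id}\t{r.subject}\t{r.habitat}\t{day}\n")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; tips must be labeled with OTU ids."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError(f"{path}: duplicate tip labels in tree")
    return tree


# ---------------------------------------------------------------------------
# table transforms
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged). Drawing
    ``depth`` reads without replacement from a sample's read pool is a
    multivariate hypergeometric draw over its OTU counts. The same seed
    yields a bit-identical result.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        logger.info(
            "rarefy: dropped %d/%d samples below depth %d: %s",
            len(dropped), len(table.sample_ids), depth, dropped,
        )
    out = {}
    for s in kept:
        col = table.df[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.otu_ids, columns=kept, dtype=np.int64)
    return CountTable(df)


def filter_low_prevalence(table: CountTable, min_fraction: float) -> CountTable:
    """Keep OTUs present (count > 0) in at least ``ceil(min_fraction * n_samples)``
    samples.

    The ceiling makes a "1% of samples" bound conservative on small n.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    n_samples = len(table.sample_ids)
    min_count = ceil(min_fraction * n_samples)
    occupancy = (table.df > 0).sum(axis=1)
    return CountTable(table.df.loc[occupancy >= min_count])


def collapse_taxonomy(table: CountTable, taxonomy: TaxonomyMap,
                      rank: str) -> CountTable:
    """Sum counts over OTUs sharing the lineage prefix through ``rank``.

    Per-sample totals are conserved exactly; the output row labels are the
    ``;``-joined lineage prefixes.
    """
    _rank_index(rank)  # validates rank
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise KeyError(f"OTUs without taxonomy: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    keys = ["; ".join(taxonomy.prefix(o, rank)) for o in table.otu_ids]
    collapsed = table.df.groupby(pd.Index(keys, name="taxon"), sort=True).sum()
    return CountTable(collapsed)


def order_series(records: Sequence[SampleRecord], subject: str,
                 habitat: str) -> list[SampleRecord]:
    """Day-ordered sampling events for one (subject, habitat) series."""
    series = [r for r in records if r.matches(subject, habitat) and r.day is not None]
    if not series:
        raise ValueError(f"no samples match subject={subject!r} habitat={habitat!r}")
    series.sort(key=lambda r: r.day)
    days = [r.day for r in series]
    if len(set(days)) != len(days):
        raise ValueError(
            f"duplicate collection days in series {subject}/{habitat}"
        )
    return series
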