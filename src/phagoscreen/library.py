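"""Screen library index, sgRNA counting from reads, and count-matrix assembly.

The library index is a TSV of guide records (guide id, target gene, spacer
sequence, control flag). Reads are counted against the index by exact string
match on the spacer: either at a fixed offset (``exact`` mode) or by scanning
the read for any library spacer (``substring`` mode, the default, since the
amplicon offset of the spacer within a read depends on the PCR design and is
often staggered). There is no mismatch tolerance and, by default, no
reverse-complement search: amplicon orientation is fixed by the PCR primers.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved pseudo-gene label shared by all non-targeting control guides.
CONTROL_GENE = "CONTROL"

_DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class LibraryError(ValueError):
    """Malformed or internally inconsistent library index."""


@dataclass(frozen=True)
class LibraryEntry:
    """One sgRNA record: identifier, target gene symbol, spacer, control flag."""

    guide_id: str
    gene: str
    spacer: str
    is_control: bool = False


@dataclass
class LibraryIndex:
    """Validated guide -> gene map with spacer sequences.

    Invariants enforced at construction: unique guide ids, one common spacer
    length over {A,C,G,T}, non-empty gene symbol for targeting guides, a
    shared pseudo-gene label (:data:`CONTROL_GENE`) for controls, and unique
    spacer sequences (a duplicated spacer makes read assignment ambiguous, so
    it is rejected here rather than at count time).
    """

    entries: list[LibraryEntry]
    _by_spacer: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise LibraryError("library index is empty")
        seen_ids: set[str] = set()
        lengths = {len(e.spacer) for e in self.entries}
        if len(lengths) != 1:
            raise LibraryError(f"mixed spacer lengths in library: {sorted(lengths)}")
        by_spacer: dict[str, str] = {}
        for e in self.entries:
            if e.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {e.guide_id!r}")
            seen_ids.add(e.guide_id)
            bad = set(e.spacer) - _DNA_ALPHABET
            if bad:
                raise LibraryError(
                    f"guide {e.guide_id!r}: spacer contains non-ACGT symbols {sorted(bad)}"
                )
            if not e.is_control and not e.gene:
                raise LibraryError(f"targeting guide {e.guide_id!r} has no gene")
            if e.is_control and e.gene != CONTROL_GENE:
                raise LibraryError(
                    f"control guide {e.guide_id!r} must carry gene label {CONTROL_GENE!r}"
                )
            if e.spacer in by_spacer:
                raise LibraryError(
                    f"duplicate spacer shared by {by_spacer[e.spacer]!r} and "
                    f"{e.guide_id!r}: ambiguous at count time"
                )
            by_spacer[e.spacer] = e.guide_id
        object.__setattr__(self, "_by_spacer", by_spacer)

    @property
    def spacer_length(self) -> int:
        return len(self.entries[0].spacer)

    @property
    def guide_ids(self) -> list[str]:
        return [e.guide_id for e in self.entries]

    @property
    def n_controls(self) -> int:
        return sum(e.is_control for e in self.entries)

    def guide_to_gene(self) -> dict[str, str]:
        return {e.guide_id: e.gene for e in self.entries}

    def spacer_map(self) -> Mapping[str, str]:
        """spacer -> guide_id (unique by construction)."""
        return dict(self._by_spacer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [e.guide_id for e in self.entries],
                "gene": [e.gene for e in self.entries],
                "spacer": [e.spacer for e in self.entries],
                "is_control": [e.is_control for e in self.entries],
            }
        )

    def __len__(self) -> int:
        return len(self.entries)


def load_library(path: str | Path) -> LibraryIndex:
    """Read a library index TSV with columns guide_id, gene, spacer[, is_control].

    ``is_control`` accepts 0/1, true/false (any case). Control rows may leave
    ``gene`` empty; it is replaced by the reserved pseudo-gene label.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise LibraryError(f"cannot parse {path}: {exc}") from exc
    required = {"guide_id", "gene", "spacer"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing columns {sorted(missing)}")
    entries: list[LibraryEntry] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        guide_id = row_d["guide_id"].strip()
        spacer = row_d["spacer"].strip().upper()
        if not guide_id or not spacer:
            raise LibraryError(f"{path} line {lineno}: empty guide_id or spacer")
        is_control = _parse_flag(row_d.get("is_control", "0"), path, lineno)
        gene = row_d["gene"].strip()
        if is_control:
            gene = CONTROL_GENE
        entries.append(LibraryEntry(guide_id, gene, spacer, is_control))
    return LibraryIndex(entries)


def write_library(index: LibraryIndex, path: str | Path) -> None:
    index.to_frame().to_csv(path, sep="\t", index=False)


def _parse_flag(value: str, path: Path, lineno: int) -> bool:
    v = str(value).strip().lower()
    if v in {"", "0", "false", "no"}:
        return False
    if v in {"1", "true", "yes"}:
        return True
    raise LibraryError(f"{path} line {lineno}: bad is_control value {value!r}")


@dataclass
class CountingReport:
    """Read-accounting per sample: matched + unmatched = total."""

    total_reads: int = 0
    matched_reads: int = 0

    @property
    def unmatched_reads(self) -> int:
        return self.total_reads - self.matched_reads

    def to_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "matched_reads": self.matched_reads,
            "unmatched_reads": self.unmatched_reads,
        }


def _iter_fastq(path: Path) -> Iterator[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


def count_reads(
    reads: Iterable[str] | str | Path,
    index: LibraryIndex,
    mode: str = "substring",
    offset: int = 0,
    reverse_complement: bool = False,
) -> tuple[pd.Series, CountingReport]:
    """Count reads against the library; each read increments at most one guide.

    Parameters
    ----------
    reads
        FASTQ path (plain or .gz) or an iterable of read sequences.
    mode
        ``"substring"`` scans each read left to right for any library spacer
        (left-most match wins); ``"exact"`` compares the L-mer at ``offset``.
    reverse_complement
        Also search the reverse complement of each read when the forward
        strand yields no match.

    Returns the per-guide count column (indexed by guide id, in library
    order) and a :class:`CountingReport` conserving the read total.
    """
    if mode not in {"exact", "substring"}:
        raise ValueError(f"unknown counting mode {mode!r}")
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(Path(reads))
    L = index.spacer_length
    spacers = index.spacer_map()
    counts: dict[str, int] = dict.fromkeys(index.guide_ids, 0)
    report = CountingReport()
    for read in reads:
        read = read.upper()
        report.total_reads += 1
        guide = _match_read(read, spacers, L, mode, offset)
        if guide is None and reverse_complement:
            guide = _match_read(read.translate(_COMPLEMENT)[::-1], spacers, L, mode, offset)
        if guide is not None:
            counts[guide] += 1
            report.matched_reads += 1
    return pd.Series(counts, name="count", dtype=np.int64), report


def _match_read(
    read: str, spacers: Mapping[str, str], L: int, mode: str, offset: int
) -> str | None:
    if mode == "exact":
        return spacers.get(read[offset : offset + L])
    for i in range(len(read) - L + 1):
        hit = spacers.get(read[i : i + L])
        if hit is not None:
            return hit
    return None


#: Sorted-fraction labels the screen design recognizes.
KNOWN_CONDITIONS = (
    "PhagoNeg",
    "PhagoEarly",
    "PhagoLate",
    "Input",
    "Undiff",
    "Plasmid",
)


@dataclass
class CountMatrix:
    """Guides x samples integer counts with per-sample condition metadata.

    ``counts`` is indexed by guide id with one column per sample id;
    ``samples`` carries sample_id, condition and replicate. Conditions outside
    :data:`KNOWN_CONDITIONS` are allowed (labelled free-form) but contrasts in
    the differential step require >=2 replicates per condition.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    guide_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        required = {"sample_id", "condition", "replicate"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"sample metadata needs columns {sorted(required)}")
        if self.samples["sample_id"].duplicated().any():
            dupes = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"sample_id collision: {sorted(set(dupes))}")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            self.counts = self.counts[list(self.samples["sample_id"])]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate guide ids in count matrix")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples["condition"] == condition
        return list(self.samples.loc[sel, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        meta = self.samples[self.samples["sample_id"].isin(sample_ids)]
        return CountMatrix(self.counts[list(meta["sample_id"])], meta, self.guide_to_gene)

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]


def merge_counts(
    columns: Mapping[str, pd.Series],
    samples: pd.DataFrame,
    index: LibraryIndex | None = None,
) -> CountMatrix:
    """Assemble per-sample count columns into a :class:`CountMatrix`.

    Column order follows the metadata row order; guides absent from a column
    are filled with zero. When a library ``index`` is given, its guide order
    defines the row order and rows are restricted to library guides.
    """
    missing = [s for s in samples["sample_id"] if s not in columns]
    if missing:
        raise ValueError(f"no count column for samples {missing}")
    frame = pd.DataFrame({sid: columns[sid] for sid in samples["sample_id"]})
    if index is not None:
        extra = set(frame.index) - set(index.guide_ids)
        if extra:
            raise ValueError(f"count rows not in library index: {sorted(extra)[:5]}")
        frame = frame.reindex(index.guide_ids)
    frame = frame.fillna(0).astype(np.int64)
    g2g = index.guide_to_gene() if index is not None else None
    return CountMatrix(frame, samples, g2g)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV: guide_id, gene, then one column per sample."""
    out = matrix.counts.copy()
    gene = (
        pd.Series(matrix.guide_to_gene).reindex(out.index)
        if matrix.guide_to_gene
        else pd.Series("", index=out.index)
    )
    out.insert(0, "gene", gene)
    out.index.name = "guide_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path, samples: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    g2g = df["gene"].to_dict() if "gene" in df.columns else None
    counts = df.drop(columns=["gene"], errors="ignore")
    return CountMatrix(counts, samples, g2g)


def write_report(reports: Mapping[str, CountingReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: r.to_dict() for k, r in reports.items()}, fh, indent=2)
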