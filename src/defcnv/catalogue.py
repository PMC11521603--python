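"""Bovine β-defensin gene catalogue.

The catalogue lists every annotated β-defensin region on the ARS-UCD1.2
assembly with 1-based inclusive coordinates, the number of assembly copies the
region's assay group represents, and the human orthologue where one exists.
Near-identical paralogous regions that cannot be distinguished by short-read
mapping (the three *DEFB103* annotations) share one ``assay_group`` and are
quantified jointly downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneCatalogue",
    "CatalogueError",
    "NoCysteineError",
    "TailFeatures",
    "load_catalogue",
    "default_catalogue",
    "to_bed",
    "from_bed",
    "find_overlapping_pairs",
    "c_terminal_tail_length",
    "count_ser_thr_in_tail",
    "tail_features",
]

CATALOGUE_COLUMNS = [
    "symbol",
    "chromosome",
    "start",
    "end",
    "reference_copies",
    "assay_group",
    "orthologue",
    "protein_sequence",
]


class CatalogueError(ValueError):
    """Raised when a catalogue file violates the record invariants."""


class NoCysteineError(ValueError):
    """Raised for protein sequences without a cysteine: the C-terminal tail
    is undefined, which is distinct from a tail of length zero."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene region.

    Coordinates are 1-based inclusive, as printed in genome browsers.
    ``reference_copies`` is the number of assembly copies represented by the
    record's assay group (3 for the *DEFB103* group, 1 otherwise).
    """

    symbol: str
    chromosome: str
    start: int
    end: int
    reference_copies: int = 1
    assay_group: str | None = None
    orthologue: str | None = None
    protein_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CatalogueError(f"{self.symbol}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise CatalogueError(
                f"{self.symbol}: end ({self.end}) < start ({self.start})"
            )
        if self.reference_copies < 1:
            raise CatalogueError(
                f"{self.symbol}: reference_copies must be >= 1, got {self.reference_copies}"
            )
        if self.assay_group is None:
            object.__setattr__(self, "assay_group", self.symbol)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GeneRecord") -> bool:
        """Closed-interval overlap on the same chromosome (touching counts)."""
        return self.chromosome == other.chromosome and max(
            self.start, other.start
        ) <= min(self.end, other.end)


@dataclass
class GeneCatalogue:
    """Ordered collection of :class:`GeneRecord` with unique symbols."""

    records: list[GeneRecord] = field(default_factory=list)
    assembly_name: str = "ARS-UCD1.2"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        group_copies: dict[str, int] = {}
        for rec in self.records:
            if rec.symbol in seen:
                raise CatalogueError(f"duplicate symbol {rec.symbol!r}")
            seen.add(rec.symbol)
            prev = group_copies.setdefault(rec.assay_group, rec.reference_copies)
            if prev != rec.reference_copies:
                raise CatalogueError(
                    f"assay group {rec.assay_group!r} mixes reference_copies "
                    f"{prev} and {rec.reference_copies}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, symbol: str) -> GeneRecord:
        for rec in self.records:
            if rec.symbol == symbol:
                return rec
        raise KeyError(symbol)

    @property
    def symbols(self) -> list[str]:
        return [rec.symbol for rec in self.records]

    @property
    def assay_groups(self) -> list[str]:
        """Assay group keys in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.assay_group not in out:
                out.append(rec.assay_group)
        return out

    def assay_group_map(self) -> dict[str, str]:
        """symbol -> assay_group."""
        return {rec.symbol: rec.assay_group for rec in self.records}

    def expected_cn(self) -> pd.Series:
        """Expected diploid copy number per assay group (2 x reference_copies)."""
        vals = {
            rec.assay_group: 2 * rec.reference_copies for rec in self.records
        }
        return pd.Series(vals, name="expected_cn").loc[self.assay_groups]

    def region_lengths(self) -> pd.Series:
        """Summed region length (bp) per assay group."""
        lengths: dict[str, int] = {}
        for rec in self.records:
            lengths[rec.assay_group] = lengths.get(rec.assay_group, 0) + rec.length
        return pd.Series(lengths, name="length_bp").loc[self.assay_groups]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "symbol": r.symbol,
                    "chromosome": r.chromosome,
                    "start": r.start,
                    "end": r.end,
                    "reference_copies": r.reference_copies,
                    "assay_group": r.assay_group,
                    "orthologue": r.orthologue,
                    "protein_sequence": r.protein_sequence,
                }
                for r in self.records
            ],
            columns=CATALOGUE_COLUMNS,
        )

    def with_protein_sequences(self, sequences: dict[str, str]) -> "GeneCatalogue":
        """Return a copy with protein sequences attached where provided."""
        recs = [
            replace(r, protein_sequence=sequences.get(r.symbol, r.protein_sequence))
            for r in self.records
        ]
        return GeneCatalogue(recs, assembly_name=self.assembly_name)


def _parse_coord(value: str, line_no: int, column: str) -> int:
    # Table-style coordinates may carry thousands separators.
    text = str(value).strip().replace(",", "")
    try:
        return int(text)
    except ValueError:
        raise CatalogueError(
            f"line {line_no}: cannot parse {column} value {value!r} as an integer"
        ) from None


def load_catalogue(path: str | Path, assembly_name: str = "ARS-UCD1.2") -> GeneCatalogue:
    """Load a gene catalogue from a TSV file.

    Required columns: symbol, chromosome, start, end. Optional columns:
    reference_copies (default 1), assay_group (default = symbol), orthologue,
    protein_sequence. Coordinates may contain commas as thousands separators.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"symbol", "chromosome", "start", "end"} - set(df.columns)
    if missing:
        raise CatalogueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        symbol = row["symbol"].strip()
        if not symbol:
            raise CatalogueError(f"line {line_no}: empty symbol")
        records.append(
            GeneRecord(
                symbol=symbol,
                chromosome=row["chromosome"].strip(),
                start=_parse_coord(row["start"], line_no, "start"),
                end=_parse_coord(row["end"], line_no, "end"),
                reference_copies=(
                    _parse_coord(row["reference_copies"], line_no, "reference_copies")
                    if row.get("reference_copies", "").strip()
                    else 1
                ),
                assay_group=row.get("assay_group", "").strip() or None,
                orthologue=(
                    row.get("orthologue", "").strip() or None
                    if row.get("orthologue", "").strip().lower() != "none"
                    else None
                ),
                protein_sequence=row.get("protein_sequence", "").strip() or None,
            )
        )
    return GeneCatalogue(records, assembly_name=assembly_name)


def default_catalogue() -> GeneCatalogue:
    """The packaged bovine β-defensin catalogue (54 annotated regions)."""
    ref = importlib.resources.files("defcnv").joinpath("data/catalogue.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_catalogue(path)


def to_bed(catalogue: GeneCatalogue) -> str:
    """Render the catalogue as 4-column BED text.

    BED is 0-based half-open, so a 1-based inclusive record (start, end)
    becomes (start - 1, end). The name column carries the gene symbol.
    """
    lines = [
        f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.symbol}" for r in catalogue
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_bed(catalogue: GeneCatalogue, path: str | Path) -> None:
    Path(path).write_text(to_bed(catalogue))


def from_bed(source: str | Path) -> GeneCatalogue:
    """Parse 4-column BED text (or a path to it) back into a catalogue.

    Only coordinates and symbols survive a BED round-trip; assay grouping and
    copy counts revert to singleton defaults.
    """
    if isinstance(source, Path) or (
        "\t" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    records = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise CatalogueError(f"BED line {line_no}: expected 4 columns")
        chrom, start0, end, name = fields[:4]
        records.append(
            GeneRecord(
                symbol=name,
                chromosome=chrom,
                start=int(start0) + 1,
                end=int(end),
            )
        )
    return GeneCatalogue(records)


def find_overlapping_pairs(catalogue: GeneCatalogue) -> list[tuple[str, str]]:
    """Unordered pairs of symbols whose intervals overlap on one chromosome.

    Overlap is closed-interval: records sharing only an endpoint are reported.
    Each pair appears once, in catalogue order.
    """
    pairs = []
    recs = catalogue.records
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if a.overlaps(b):
                pairs.append((a.symbol, b.symbol))
    return pairs


def _tail_start(protein_sequence: str) -> int:
    if not protein_sequence:
        raise NoCysteineError("empty protein sequence")
    last_c = protein_sequence.rfind("C")
    if last_c == -1:
        raise NoCysteineError("sequence contains no cysteine; tail undefined")
    return last_c + 1


def c_terminal_tail_length(protein_sequence: str) -> int:
    """Number of residues strictly after the last cysteine.

    β-defensins end their conserved six-cysteine core at the final cysteine;
    residues beyond it form the C-terminal tail, which in some family members
    is long and heavily O-glycosylated. Raises :class:`NoCysteineError` for
    sequences without any cysteine.
    """
    return len(protein_sequence) - _tail_start(protein_sequence)


def count_ser_thr_in_tail(protein_sequence: str) -> int:
    """Serine + threonine count in the C-terminal tail.

    A documented proxy for O-glycosylation potential: mucin-type O-glycans
    attach to Ser/Thr hydroxyls, so a Ser/Thr-free tail cannot carry them.
    """
    tail = protein_sequence[_tail_start(protein_sequence) :]
    return tail.count("S") + tail.count("T")


@dataclass(frozen=True)
class TailFeatures:
    """C-terminal tail summary for one protein."""

    tail_length: int
    is_long: bool
    n_ser_thr: int
    long_cutoff: int


def tail_features(protein_sequence: str, long_cutoff: int = 20) -> TailFeatures:
    """Tail length, long-tail flag and Ser/Thr count in one pass.

    ``long_cutoff`` is the residue count above which a tail counts as "long";
    the default of 20 separates the extended glycosylated tails (e.g. 45
    residues) from the short tails typical of purely antimicrobial members.
    """
    n = c_terminal_tail_length(protein_sequence)
    return TailFeatures(
        tail_length=n,
        is_long=n > long_cutoff,
        n_ser_thr=count_ser_thr_in_tail(protein_sequence),
        long_cutoff=long_cutoff,
    )
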