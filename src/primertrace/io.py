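"""Reading and writing the pipeline's external formats.

Count tables and sample metadata travel as TSV (samples as rows — desk-scale,
diffable, no binary dependency); ASV representative sequences as FASTA.
Parsing is strict: malformed counts, duplicate identifiers and unknown
metadata categories are rejected with the offending location, never coerced.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROLES = ("soil", "substrate", "primer", "test")
SOIL_TYPES = ("DF", "PS", "none")
SUBSTRATE_TYPES = ("Oat", "Hemp", "none")

#: IUPAC nucleotide one-letter codes (uppercase, post U→T mapping).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

METADATA_COLUMNS = ("sample_id", "role", "soil_type", "substrate_type", "replicate")


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata for one sequenced sample.

    ``role`` is the community's place in the experimental design: a source
    soil, a source substrate, a trained ("primer") community, or a Phase-II
    test community.  ``soil_type``/``substrate_type`` are "none" when the
    role makes them inapplicable.
    """

    sample_id: str
    role: str
    soil_type: str = "none"
    substrate_type: str = "none"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.sample_id!r}")
        if self.soil_type not in SOIL_TYPES:
            raise ValueError(f"unknown soil_type {self.soil_type!r} for sample {self.sample_id!r}")
        if self.substrate_type not in SUBSTRATE_TYPES:
            raise ValueError(
                f"unknown substrate_type {self.substrate_type!r} for sample {self.sample_id!r}"
            )
        if self.role == "soil" and self.substrate_type != "none":
            raise ValueError(f"soil sample {self.sample_id!r} must have substrate_type 'none'")
        if self.role == "substrate" and self.soil_type != "none":
            raise ValueError(f"substrate sample {self.sample_id!r} must have soil_type 'none'")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer for {self.sample_id!r}")


@dataclass(frozen=True)
class AsvRecord:
    """One denoised amplicon sequence variant (id + representative sequence)."""

    asv_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = next((i for i, c in enumerate(self.sequence) if c not in IUPAC_CODES), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {self.sequence[bad]!r} at position {bad} in {self.asv_id!r}"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.asv_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


class CountTable:
    """Samples × ASVs matrix of read counts with per-sample metadata.

    ``counts`` is an integer DataFrame indexed by sample id with ASV ids as
    columns; ``metadata`` is indexed by sample id with columns role,
    soil_type, substrate_type, replicate.  Every sample must have exactly one
    metadata record; labels must be unique; counts must be non-negative.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        metadata = metadata.copy()
        if counts.shape[0] == 0:
            raise ValueError("no samples")
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dupes}")
        if (counts.to_numpy() < 0).any():
            s, a = next(zip(*((counts.to_numpy() < 0).nonzero())))
            raise ValueError(
                f"negative count at sample {counts.index[s]!r}, ASV {counts.columns[a]!r}"
            )
        missing = set(counts.index) - set(metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        # validate each metadata row through the dataclass
        for sid, row in metadata.loc[list(counts.index)].iterrows():
            SampleMetadata(
                sample_id=str(sid),
                role=row["role"],
                soil_type=row["soil_type"],
                substrate_type=row["substrate_type"],
                replicate=int(row["replicate"]),
            )
        self.counts = counts.astype("int64")
        self.metadata = metadata.loc[list(counts.index)]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_depths(self) -> pd.Series:
        """Total reads per sample (the sequencing depth after processing)."""
        return self.counts.sum(axis=1)

    def asv_totals(self) -> pd.Series:
        """Total reads per ASV summed over all samples."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)], self.metadata)

    def select_role(self, role: str) -> "CountTable":
        keep = self.metadata.index[self.metadata["role"] == role]
        keep = [s for s in self.sample_ids if s in set(keep)]
        return self.subset_samples(keep)

    def drop_absent_asvs(self) -> "CountTable":
        present = self.counts.columns[self.counts.sum(axis=0) > 0]
        return CountTable(self.counts[present], self.metadata)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.equals(
            other.metadata.loc[self.metadata.index]
        )


# -- metadata ------------------------------------------------------------------


def _canon(value: str, options: tuple[str, ...], field: str) -> str:
    for opt in options:
        if value.strip().lower() == opt.lower():
            return opt
    raise ValueError(f"unknown {field} {value!r}; expected one of {options}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV; enum fields are case-insensitive on read."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    df["role"] = [_canon(v, ROLES, "role") for v in df["role"]]
    df["soil_type"] = [_canon(v, SOIL_TYPES, "soil_type") for v in df["soil_type"]]
    df["substrate_type"] = [
        _canon(v, SUBSTRATE_TYPES, "substrate_type") for v in df["substrate_type"]
    ]
    df["replicate"] = [_strict_int(v, f"replicate of sample {s!r}")
                       for v, s in zip(df["replicate"], df["sample_id"])]
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.reset_index()
    if "index" in out.columns:
        out = out.rename(columns={"index": "sample_id"})
    out.to_csv(path, sep="\t", index=False, columns=list(METADATA_COLUMNS))


# -- count tables --------------------------------------------------------------


def _strict_int(text: str, where: str) -> int:
    try:
        return int(text)
    except (TypeError, ValueError):
        raise ValueError(f"invalid integer {text!r} at {where}") from None


def read_count_table(path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a TSV count table (first column sample ids, header ASV ids).

    Integer parsing is strict: a cell like ``2.5`` is an error naming the
    cell, never silently truncated.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.shape[0] == 0:
        raise ValueError("no samples")
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype="int64")
    for asv in raw.columns:
        col = raw[asv]
        parsed[asv] = [
            _strict_int(v, f"sample {s!r}, ASV {asv!r}") for s, v in col.items()
        ]
    metadata = read_metadata(metadata_path)
    return CountTable(parsed, metadata)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


# -- FASTA ---------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[AsvRecord]:
    """Read ASV representative sequences.

    The id is the header's first whitespace-delimited token; sequences are
    uppercased and U is mapped to T.  Duplicate ids, empty sequences and
    non-IUPAC characters are rejected.
    """
    records: list[AsvRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate ASV id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        records.append(AsvRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[AsvRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.asv_id, description="") for r in records),
        str(path),
        "fasta-2line",
    )


def match_ids_by_sequence(
    queries: Sequence[AsvRecord], references: Sequence[AsvRecord]
) -> dict[str, str]:
    """Map query ids to reference ids by exact sequence identity.

    Used to harmonise ASV id namespaces produced by separate denoising runs;
    sequences are compared after the normalisation applied by read_fasta.
    """
    by_seq = {r.sequence: r.asv_id for r in references}
    return {q.asv_id: by_seq[q.sequence] for q in queries if q.sequence in by_seq}


# -- reports -------------------------------------------------------------------


def _format_cell(value: object, decimals: int = 2) -> str:
    if isinstance(value, float):
        q = decimal.Decimal(repr(value)).quantize(
            decimal.Decimal(10) ** -decimals, rounding=decimal.ROUND_HALF_UP
        )
        return f"{q:.{decimals}f}"
    return str(value)


def write_report(rows: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    """Write a summary table as TSV with a stable column order.

    Float columns are rendered with ``decimals`` places, rounding halves away
    from zero (0.025 → "0.03"), matching the granularity of the published
    distance summaries.  An empty summary yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, rows.columns)) + "\n")
        for _, row in rows.iterrows():
            fh.write("\t".join(_format_cell(v, decimals) for v in row) + "\n")
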