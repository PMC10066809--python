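"""Core data containers and tab-separated I/O for metabarcoding diet data.

A :class:`Dataset` bundles three tables that travel together through the
pipeline:

* a count table (taxa x samples, non-negative integers),
* a taxonomy table mapping each taxon to a ranked lineage and a marker gene
  (16S or 18S),
* a sample-metadata table describing each column (gut or water sample,
  predator species, station, campaign, replicate).

All on-disk formats are plain UTF-8 TSV with a header row, taxa as rows and
samples as columns, matching the usual ASV-table exports of amplicon
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Ordered lineage ranks, coarse to fine.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

MARKERS = ("16S", "18S")
SAMPLE_TYPES = ("gut", "water")

TAXONOMY_COLUMNS = ("taxon_id",) + RANKS + ("marker",)
METADATA_COLUMNS = (
    "sample_id",
    "sample_type",
    "predator_species",
    "station",
    "campaign",
    "replicate_id",
)


class DataModelError(ValueError):
    """Base class for validation failures in the data model."""


class SchemaError(DataModelError):
    """A table is missing required columns or has duplicate identifiers."""


class CrossReferenceError(DataModelError):
    """Counts, taxonomy and metadata do not reference each other consistently."""


class DomainError(DataModelError):
    """A value is outside its domain (negative count, bad marker, ...)."""


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon (ASV or aggregated label) with its ranked lineage.

    Missing ranks are encoded as the empty string, never dropped, so the
    lineage tuple always has one entry per rank in :data:`RANKS`.
    """

    taxon_id: str
    lineage: tuple[str, ...]
    marker: str

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise DomainError(
                f"taxon {self.taxon_id!r}: lineage must have {len(RANKS)} ranks, "
                f"got {len(self.lineage)}"
            )
        if self.marker not in MARKERS:
            raise DomainError(
                f"taxon {self.taxon_id!r}: marker must be one of {MARKERS}, "
                f"got {self.marker!r}"
            )

    def rank_label(self, rank: str) -> str:
        """Label at ``rank``, empty string if unassigned."""
        return self.lineage[RANKS.index(rank)]

    def parent_label(self, rank: str) -> str:
        """Nearest non-empty label strictly above ``rank`` (or 'root')."""
        idx = RANKS.index(rank)
        for r in range(idx - 1, -1, -1):
            if self.lineage[r]:
                return self.lineage[r]
        return "root"


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequencing sample (gut replicate or water replicate)."""

    sample_id: str
    sample_type: str
    predator_species: str
    station: str
    campaign: str
    replicate_id: str

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise DomainError(
                f"sample {self.sample_id!r}: sample_type must be one of "
                f"{SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.sample_type == "gut" and not self.predator_species:
            raise DomainError(
                f"gut sample {self.sample_id!r} must carry a predator_species"
            )
        if self.sample_type == "water" and self.predator_species:
            raise DomainError(
                f"water sample {self.sample_id!r} must not carry a "
                f"predator_species (got {self.predator_species!r})"
            )


@dataclass
class Dataset:
    """Count table plus taxonomy and sample metadata, validated as a unit.

    Attributes
    ----------
    counts
        Integer DataFrame, index = taxon ids, columns = sample ids.
    taxonomy
        Mapping taxon_id -> :class:`TaxonRecord`.
    metadata
        Mapping sample_id -> :class:`SampleRecord`.
    provenance
        Free-text log lines appended by pipeline stages (exclusions,
        aggregation, filtering); carried along, never parsed.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonRecord]
    metadata: dict[str, SampleRecord]
    provenance: list[str] = field(default_factory=list)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "Dataset":
        """Check all invariants; raise a typed error on the first violation."""
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate taxon ids in count table: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids in count table: {dups}")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                # allow float storage only if every entry is integral
                if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                    bad = np.argwhere(arr != np.floor(arr))
                    r, c = bad[0]
                    raise DomainError(
                        f"non-integer count at taxon {counts.index[r]!r}, "
                        f"sample {counts.columns[c]!r}: {arr[r, c]}"
                    )
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise DomainError(
                    f"negative count at taxon {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]}"
                )
        missing_tax = [t for t in counts.index if t not in self.taxonomy]
        if missing_tax:
            raise CrossReferenceError(
                f"taxa absent from taxonomy table: {missing_tax}"
            )
        missing_meta = [s for s in counts.columns if s not in self.metadata]
        if missing_meta:
            raise CrossReferenceError(
                f"samples absent from metadata table: {missing_meta}"
            )
        markers = {self.taxonomy[t].marker for t in counts.index}
        if len(markers) > 1:
            raise DomainError(
                f"dataset mixes markers {sorted(markers)}; one marker per dataset"
            )
        return self

    # -- convenience accessors ----------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def marker(self) -> str:
        """The single marker shared by all taxa ('16S' or '18S')."""
        markers = {rec.marker for rec in self.taxonomy.values()}
        if len(markers) != 1:
            raise DomainError(f"dataset mixes markers {sorted(markers)}")
        return markers.pop()

    def sample_ids(
        self,
        sample_type: str | None = None,
        predator: str | None = None,
        station: str | None = None,
        campaign: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata restrictions, in table order."""
        out = []
        for sid in self.counts.columns:
            rec = self.metadata[sid]
            if sample_type is not None and rec.sample_type != sample_type:
                continue
            if predator is not None and rec.predator_species != predator:
                continue
            if station is not None and rec.station != station:
                continue
            if campaign is not None and rec.campaign != campaign:
                continue
            out.append(sid)
        return out

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "Dataset":
        """New Dataset restricted to ``taxon_ids`` (kept in current order)."""
        keep = [t for t in self.counts.index if t in set(taxon_ids)]
        return Dataset(
            counts=self.counts.loc[keep].copy(),
            taxonomy={t: self.taxonomy[t] for t in keep},
            metadata=dict(self.metadata),
            provenance=list(self.provenance),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "Dataset":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return Dataset(
            counts=self.counts[keep].copy(),
            taxonomy=dict(self.taxonomy),
            metadata={s: self.metadata[s] for s in keep},
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    # -- frame views ---------------------------------------------------------

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_id": t, **dict(zip(RANKS, rec.lineage)), "marker": rec.marker}
            for t, rec in self.taxonomy.items()
        ]
        return pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS))

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "sample_type": rec.sample_type,
                "predator_species": rec.predator_species,
                "station": rec.station,
                "campaign": rec.campaign,
                "replicate_id": rec.replicate_id,
            }
            for s, rec in self.metadata.items()
        ]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def load_dataset(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> Dataset:
    """Load and validate the three standard TSV tables into a Dataset.

    Raises a typed :class:`DataModelError` subclass on malformed input;
    values are never silently coerced.
    """
    counts_raw = _read_tsv(counts_path, ("taxon_id",))
    if counts_raw["taxon_id"].duplicated().any():
        dups = counts_raw["taxon_id"][counts_raw["taxon_id"].duplicated()].tolist()
        raise SchemaError(f"duplicate taxon ids in {Path(counts_path).name}: {dups}")
    counts = counts_raw.set_index("taxon_id")
    num = pd.DataFrame(index=counts.index)
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            bad = counts.index[vals.isna()][0]
            raise DomainError(
                f"non-numeric count at taxon {bad!r}, sample {col!r}: "
                f"{counts.loc[bad, col]!r}"
            )
        num[col] = vals
    counts = num
    counts.index.name = "taxon_id"

    tax_df = _read_tsv(taxonomy_path, TAXONOMY_COLUMNS)
    taxonomy: dict[str, TaxonRecord] = {}
    for _, row in tax_df.iterrows():
        rec = TaxonRecord(
            taxon_id=row["taxon_id"],
            lineage=tuple(row[r] for r in RANKS),
            marker=row["marker"],
        )
        if rec.taxon_id in taxonomy:
            raise SchemaError(f"duplicate taxon id in taxonomy: {rec.taxon_id!r}")
        taxonomy[rec.taxon_id] = rec

    meta_df = _read_tsv(metadata_path, METADATA_COLUMNS)
    metadata: dict[str, SampleRecord] = {}
    for row in meta_df.itertuples(index=False):
        rec = SampleRecord(
            sample_id=row.sample_id,
            sample_type=row.sample_type,
            predator_species=row.predator_species,
            station=row.station,
            campaign=row.campaign,
            replicate_id=row.replicate_id,
        )
        if rec.sample_id in metadata:
            raise SchemaError(f"duplicate sample id in metadata: {rec.sample_id!r}")
        metadata[rec.sample_id] = rec

    ds = Dataset(counts=counts, taxonomy=taxonomy, metadata=metadata)
    ds.validate()
    ds.counts = ds.counts.astype(np.int64)
    return ds


def validate_composition(frame: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Assert that every column of ``frame`` is a composition (sums to 1)."""
    arr = frame.to_numpy(dtype=float)
    if arr.size and np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise DomainError(
            f"negative proportion at {frame.index[r]!r}/{frame.columns[c]!r}"
        )
    sums = arr.sum(axis=0)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise DomainError(
            f"column {frame.columns[bad[0]]!r} sums to {sums[bad[0]]}, expected 1"
        )
    return frame


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/taxonomy/metadata as the three standard TSVs.

    Returns a mapping of table name to written path.  ``load_dataset`` on
    the result reproduces the Dataset exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.taxonomy_frame().to_csv(paths["taxonomy"], sep="\t", index=False)
    dataset.metadata_frame().to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def write_tables(
    bundle: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write each named DataFrame in ``bundle`` as ``<name>.tsv`` in out_dir.

    Floats are written with 17 significant digits so a re-load reproduces
    values to 1e-12 or better; integers round-trip exactly.  Returns the
    written paths (empty bundle -> empty list).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in bundle.items():
        path = out / f"{name}.tsv"
        index = frame.index.name is not None
        frame.to_csv(path, sep="\t", index=index, float_format="%.17g")
        written.append(path)
    return written


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a numeric matrix TSV written by :func:`write_tables` (indexed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def new_dataset(
    counts: pd.DataFrame,
    taxonomy: Mapping[str, TaxonRecord],
    metadata: Mapping[str, SampleRecord],
    provenance: Iterable[str] = (),
) -> Dataset:
    """Build and validate a Dataset from in-memory parts."""
    ds = Dataset(
        counts=counts,
        taxonomy=dict(taxonomy),
        metadata=dict(metadata),
        provenance=list(provenance),
    )
    return ds.validate()
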