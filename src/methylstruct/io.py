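"""Reading, writing and RPM normalization of methylRAD count matrices.

methylRAD quantifies DNA methylation as the read depth of short tags
produced by a methylation-dependent restriction enzyme at CCGG / CCWGG
sites.  The on-disk interchange format is plain tab-delimited text:

* counts TSV — header row of marker IDs, first column of individual IDs,
  integer read-coverage cells.  A zero means the site was uncovered /
  unmethylated in that library; empty cells are an error, never imputed.
* sample metadata TSV — columns ``individual``, ``site``, ``library_size``
  (high-quality read total per library).
* marker metadata TSV — columns ``marker``, ``motif`` (CCGG or CCWGG) and
  optionally ``contig``, ``position`` (1-based; methylRAD tags are treated
  as strandless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylRadCounts",
    "SampleMetadata",
    "RpmMatrix",
    "ValidationError",
    "read_counts",
    "write_counts",
    "compute_rpm",
    "write_rpm",
]

VALID_MOTIFS = frozenset({"CCGG", "CCWGG"})


class ValidationError(ValueError):
    """Input file or matrix violates the format contract."""


@dataclass
class SampleMetadata:
    """Per-individual sampling information.

    ``site`` maps each individual to one of the K sampling locations;
    discriminant fitting requires every site to have at least two members.
    """

    individuals: list[str]
    site: dict[str, str]
    longitude: dict[str, float] = field(default_factory=dict)
    latitude: dict[str, float] = field(default_factory=dict)

    def sites_of(self, individuals: list[str]) -> np.ndarray:
        return np.asarray([self.site[i] for i in individuals], dtype=object)

    @property
    def n_sites(self) -> int:
        return len(set(self.site.values()))


@dataclass
class MethylRadCounts:
    """Integer read coverage per individual x marker, with library totals.

    ``library_sizes`` are the per-library high-quality read counts used as
    the RPM denominator.  ``motif`` labels each marker CCGG or CCWGG;
    ``coords`` optionally places a marker on a contig (1-based position).
    """

    individuals: list[str]
    markers: list[str]
    counts: np.ndarray  # (n_individuals, n_markers) integer
    library_sizes: np.ndarray  # (n_individuals,) > 0
    motif: np.ndarray  # (n_markers,) object, in VALID_MOTIFS
    coords: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.motif = np.asarray(self.motif, dtype=object)
        n, m = len(self.individuals), len(self.markers)
        if self.counts.shape != (n, m):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({n} individuals, {m} markers)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at individual {self.individuals[i]!r}, "
                f"marker {self.markers[j]!r}"
            )
        if (self.library_sizes <= 0).any() or np.isnan(self.library_sizes).any():
            bad = int(np.flatnonzero(~(self.library_sizes > 0))[0])
            raise ValidationError(
                f"library size for individual {self.individuals[bad]!r} "
                "must be strictly positive"
            )
        if self.motif.shape != (m,):
            raise ValidationError("motif must have exactly one label per marker")
        bad_motifs = set(self.motif) - VALID_MOTIFS
        if bad_motifs:
            raise ValidationError(f"unknown motif label(s): {sorted(bad_motifs)}")
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicated individual ID")
        if len(set(self.markers)) != m:
            raise ValidationError("duplicated marker ID")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.individuals, columns=self.markers)


@dataclass
class RpmMatrix:
    """Reads-per-million methylation levels on the same axes as the counts."""

    individuals: list[str]
    markers: list[str]
    values: np.ndarray  # (n_individuals, n_markers) float, >= 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.markers)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])


def read_counts(
    count_path: str | Path,
    meta_path: str | Path,
    marker_meta_path: str | Path | None = None,
) -> tuple[MethylRadCounts, SampleMetadata]:
    """Load a counts TSV plus sample (and optionally marker) metadata.

    Marker order is preserved from the counts file header.  Every empty or
    non-integer cell, missing library size, duplicated individual, or
    individual present in only one of the two files raises
    :class:`ValidationError` naming the offending row/column.
    """
    cdf = _read_tsv(count_path)
    mdf = _read_tsv(meta_path)

    ind_col = cdf.columns[0]
    individuals = cdf[ind_col].tolist()
    markers = list(cdf.columns[1:])
    if len(set(individuals)) != len(individuals):
        dup = pd.Series(individuals)[pd.Series(individuals).duplicated()].iloc[0]
        raise ValidationError(f"duplicated individual ID {dup!r} in {count_path}")

    counts = np.empty((len(individuals), len(markers)), dtype=np.int64)
    for j, mk in enumerate(markers):
        col = cdf[mk]
        for i, raw in enumerate(col):
            s = raw.strip()
            if s == "":
                raise ValidationError(
                    f"empty count cell at individual {individuals[i]!r}, marker {mk!r}"
                )
            try:
                v = int(s)
            except ValueError as exc:
                raise ValidationError(
                    f"non-integer count {s!r} at individual {individuals[i]!r}, "
                    f"marker {mk!r}"
                ) from exc
            if v < 0:
                raise ValidationError(
                    f"negative count at individual {individuals[i]!r}, marker {mk!r}"
                )
            counts[i, j] = v

    for col in ("individual", "site", "library_size"):
        if col not in mdf.columns:
            raise ValidationError(f"metadata file missing column {col!r}")
    meta_ind = mdf["individual"].tolist()
    if len(set(meta_ind)) != len(meta_ind):
        raise ValidationError("duplicated individual ID in metadata")
    only_counts = set(individuals) - set(meta_ind)
    only_meta = set(meta_ind) - set(individuals)
    if only_counts:
        raise ValidationError(
            f"individual(s) {sorted(only_counts)} present in counts but not metadata"
        )
    if only_meta:
        raise ValidationError(
            f"individual(s) {sorted(only_meta)} present in metadata but not counts"
        )

    mrow = mdf.set_index("individual").loc[individuals]
    lib = np.empty(len(individuals), dtype=float)
    for i, raw in enumerate(mrow["library_size"]):
        s = str(raw).strip()
        if s == "":
            raise ValidationError(
                f"missing library size for individual {individuals[i]!r}"
            )
        lib[i] = float(s)
    site = dict(zip(individuals, mrow["site"].astype(str)))

    lon: dict[str, float] = {}
    lat: dict[str, float] = {}
    if "longitude" in mrow.columns and "latitude" in mrow.columns:
        for ind, lo, la in zip(individuals, mrow["longitude"], mrow["latitude"]):
            if str(lo).strip() and str(la).strip():
                lon[ind] = float(lo)
                lat[ind] = float(la)

    motif = np.asarray(["CCGG"] * len(markers), dtype=object)
    coords: dict[str, tuple[str, int]] | None = None
    if marker_meta_path is not None:
        kdf = _read_tsv(marker_meta_path)
        for col in ("marker", "motif"):
            if col not in kdf.columns:
                raise ValidationError(f"marker metadata missing column {col!r}")
        krow = kdf.set_index("marker")
        missing = [m for m in markers if m not in krow.index]
        if missing:
            raise ValidationError(f"marker(s) missing from marker metadata: {missing[:5]}")
        motif = krow.loc[markers, "motif"].to_numpy(dtype=object)
        if "contig" in krow.columns and "position" in krow.columns:
            coords = {}
            for m in markers:
                ctg = str(krow.loc[m, "contig"]).strip()
                pos = str(krow.loc[m, "position"]).strip()
                if ctg and pos:
                    coords[m] = (ctg, int(pos))

    data = MethylRadCounts(
        individuals=individuals,
        markers=markers,
        counts=counts,
        library_sizes=lib,
        motif=motif,
        coords=coords,
    )
    meta = SampleMetadata(individuals=individuals, site=site, longitude=lon, latitude=lat)
    return data, meta


def write_counts(
    data: MethylRadCounts,
    meta: SampleMetadata,
    count_path: str | Path,
    meta_path: str | Path,
    marker_meta_path: str | Path | None = None,
) -> None:
    """Write the TSV triplet read back by :func:`read_counts` (lossless)."""
    df = data.to_frame()
    df.index.name = "individual"
    df.to_csv(count_path, sep="\t")
    rows = {
        "individual": data.individuals,
        "site": [meta.site[i] for i in data.individuals],
        "library_size": [int(v) for v in data.library_sizes],
    }
    if meta.longitude:
        rows["longitude"] = [meta.longitude.get(i, "") for i in data.individuals]
        rows["latitude"] = [meta.latitude.get(i, "") for i in data.individuals]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    if marker_meta_path is not None:
        mrows = {"marker": data.markers, "motif": list(data.motif)}
        if data.coords:
            mrows["contig"] = [
                data.coords.get(m, ("", ""))[0] for m in data.markers
            ]
            mrows["position"] = [
                data.coords.get(m, ("", ""))[1] for m in data.markers
            ]
        pd.DataFrame(mrows).to_csv(marker_meta_path, sep="\t", index=False)


def compute_rpm(data: MethylRadCounts) -> RpmMatrix:
    """RPM = reads covering the site / high-quality reads in the library x 1e6.

    Applied exactly per cell with no other scaling; a zero library size must
    be handled upstream by dropping the individual explicitly.
    """
    if (data.library_sizes <= 0).any():
        raise ValidationError("library sizes must be strictly positive for RPM")
    values = data.counts / data.library_sizes[:, None] * 1_000_000.0
    return RpmMatrix(individuals=list(data.individuals), markers=list(data.markers), values=values)


def write_rpm(rpm: RpmMatrix, path: str | Path) -> None:
    df = rpm.to_frame()
    df.index.name = "individual"
    df.to_csv(path, sep="\t")
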