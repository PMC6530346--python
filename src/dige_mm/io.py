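"""Core data types and tabular interchange formats.

A 2D-DiGE experiment is stored as three tables:

* a **spot table** — one row per gel spot, one column per gel x channel,
  holding integrated fluorescence volumes.  Each gel contributes two
  columns, ``<gel>.sample`` (the individually labeled sample) and
  ``<gel>.ips`` (the internal pooled standard co-separated on the same
  gel);
* a **design table** mapping each gel to its treatment group;
* an **annotation table** mapping each spot to an optional protein
  accession, gene symbol and a spot class (``plasma`` / ``cellular`` /
  ``unidentified``) used to restrict library-size computation.

Gene sets for enrichment are read from GMT files with an optional
sidecar table of expected regulation directions.

All tables are plain delimited text (tab by default, comma accepted).
Missing cells are a hard error: the upstream image analysis guarantees a
complete matrix, and zeros (detection-limit censoring) are legal values
handled by :mod:`dige_mm.preprocess`, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("sample", "ips")


class FormatError(ValueError):
    """A file does not follow the documented layout."""


class ValidationError(ValueError):
    """A parsed value violates a data-model invariant."""


class JoinError(ValueError):
    """Two tables that must describe the same gels/spots do not."""


class Group(str, Enum):
    """Treatment arm of a gel.

    ``control`` rats received a single test dwell only; ``SCB`` and
    ``DCB`` are chronic exposure to single-chamber (acidic, high-GDP)
    or dual-chamber (neutral, low-GDP) dialysis fluid; the ``_AG``
    variants add alanyl-glutamine to the respective fluid.
    """

    control = "control"
    SCB = "SCB"
    SCB_AG = "SCB_AG"
    DCB = "DCB"
    DCB_AG = "DCB_AG"

    @classmethod
    def parse(cls, label: str) -> "Group":
        norm = str(label).strip().replace("+", "_").replace("-", "_").replace(" ", "_")
        for member in cls:
            if member.name.casefold() == norm.casefold():
                return member
        allowed = ", ".join(m.name for m in cls)
        raise ValidationError(f"unknown group label {label!r}; allowed: {allowed}")


class SpotClass(str, Enum):
    """Protein class of a spot, from subcellular-localization annotation."""

    plasma = "plasma"
    cellular = "cellular"
    unidentified = "unidentified"

    @classmethod
    def parse(cls, label: str) -> "SpotClass":
        norm = str(label).strip().casefold()
        for member in cls:
            if member.name.casefold() == norm:
                return member
        allowed = ", ".join(m.name for m in cls)
        raise ValidationError(f"unknown spot class {label!r}; allowed: {allowed}")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class SpotMatrix:
    """Two-channel spot-volume matrix for one experiment.

    ``sample`` and ``ips`` are ``(n_spots, n_gels)`` arrays of
    nonnegative, finite volumes sharing the same spot and gel ordering.
    """

    spot_ids: list[str]
    gel_ids: list[str]
    sample: np.ndarray
    ips: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gel_ids = [str(g) for g in self.gel_ids]
        self.sample = np.asarray(self.sample, dtype=float)
        self.ips = np.asarray(self.ips, dtype=float)
        _check_unique(self.spot_ids, "spot_id")
        _check_unique(self.gel_ids, "gel_id")
        shape = (len(self.spot_ids), len(self.gel_ids))
        for name, arr in (("sample", self.sample), ("ips", self.ips)):
            if arr.shape != shape:
                raise ValidationError(
                    f"{name} channel has shape {arr.shape}, expected {shape}"
                )
            bad = ~np.isfinite(arr)
            if bad.any():
                s, g = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"non-finite volume in {name} channel at spot "
                    f"{self.spot_ids[s]!r}, gel {self.gel_ids[g]!r}"
                )
            neg = arr < 0
            if neg.any():
                s, g = map(int, np.argwhere(neg)[0])
                raise ValidationError(
                    f"negative volume {arr[s, g]} in {name} channel at spot "
                    f"{self.spot_ids[s]!r}, gel {self.gel_ids[g]!r}"
                )

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_gels(self) -> int:
        return len(self.gel_ids)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return self.sample if name == "sample" else self.ips

    def copy(self) -> "SpotMatrix":
        return SpotMatrix(
            list(self.spot_ids), list(self.gel_ids), self.sample.copy(), self.ips.copy()
        )


@dataclass
class DesignTable:
    """Mapping gel -> treatment group."""

    groups: dict[str, Group]

    def __post_init__(self) -> None:
        self.groups = {str(g): Group(v) for g, v in self.groups.items()}

    @property
    def gel_ids(self) -> list[str]:
        return list(self.groups)

    def group_of(self, gel_id: str) -> Group:
        return self.groups[gel_id]

    def gels_in(self, group: Group) -> list[str]:
        return [g for g, grp in self.groups.items() if grp is group]

    def group_sizes(self) -> dict[Group, int]:
        sizes = {g: 0 for g in Group}
        for grp in self.groups.values():
            sizes[grp] += 1
        return sizes

    def validate_against(self, matrix: SpotMatrix) -> None:
        """Require a one-to-one gel correspondence with ``matrix``."""
        design_gels = set(self.groups)
        matrix_gels = set(matrix.gel_ids)
        orphans = sorted(design_gels - matrix_gels)
        missing = sorted(matrix_gels - design_gels)
        if orphans or missing:
            parts = []
            if orphans:
                parts.append(f"gels in design but not in matrix: {orphans}")
            if missing:
                parts.append(f"gels in matrix but not in design: {missing}")
            raise JoinError("; ".join(parts))


@dataclass(frozen=True)
class SpotAnnotation:
    """Annotation for one spot (accession and gene may be absent)."""

    spot_id: str
    accession: Optional[str]
    gene: Optional[str]
    spot_class: SpotClass


@dataclass
class AnnotationTable:
    """Collection of per-spot annotations with matrix-order helpers."""

    records: list[SpotAnnotation]

    def __post_init__(self) -> None:
        _check_unique([r.spot_id for r in self.records], "annotated spot_id")
        self._by_spot = {r.spot_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def get(self, spot_id: str) -> SpotAnnotation:
        return self._by_spot[spot_id]

    def validate_against(self, matrix: SpotMatrix) -> None:
        matrix_spots = set(matrix.spot_ids)
        orphans = sorted(set(self._by_spot) - matrix_spots)
        if orphans:
            raise JoinError(f"annotated spots not present in matrix: {orphans[:10]}")
        missing = sorted(matrix_spots - set(self._by_spot))
        if missing:
            raise JoinError(f"matrix spots without annotation: {missing[:10]}")

    def class_mask(self, spot_ids: Sequence[str], spot_class: SpotClass) -> np.ndarray:
        """Boolean mask over ``spot_ids`` selecting spots of ``spot_class``."""
        return np.array(
            [self._by_spot[s].spot_class is spot_class for s in spot_ids], dtype=bool
        )

    def classes(self, spot_ids: Sequence[str]) -> list[SpotClass]:
        return [self._by_spot[s].spot_class for s in spot_ids]

    def accession_of(self, spot_id: str) -> Optional[str]:
        return self._by_spot[spot_id].accession

    def gene_of(self, spot_id: str) -> Optional[str]:
        return self._by_spot[spot_id].gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": [r.spot_id for r in self.records],
                "accession": [r.accession or "" for r in self.records],
                "gene": [r.gene or "" for r in self.records],
                "spot_class": [r.spot_class.value for r in self.records],
            }
        )


@dataclass
class GeneSet:
    """Named set of gene symbols, optionally with expected directions.

    ``expected_direction`` maps a member gene to ``"up"`` or ``"down"``,
    the regulation the pathway model predicts when the pathway is
    active; it drives the activation z-score.
    """

    set_id: str
    name: str
    members: set[str]
    expected_direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")
        extra = set(self.expected_direction) - self.members
        if extra:
            raise ValidationError(
                f"gene set {self.set_id!r}: directions for non-members {sorted(extra)}"
            )
        bad = {d for d in self.expected_direction.values() if d not in ("up", "down")}
        if bad:
            raise ValidationError(
                f"gene set {self.set_id!r}: directions must be 'up'/'down', got {bad}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_sep(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_spot_table(path, sep: Optional[str] = None) -> SpotMatrix:
    """Read a spot-volume table.

    The first column holds spot identifiers; remaining column names
    follow the ``<gel>.<channel>`` suffix convention with channels
    ``sample`` and ``ips``.  Both channels must be present for every
    gel.  Input ordering of spots and gels is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_infer_sep(path, sep), dtype={0: str}, float_precision="round_trip"
    )
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected spot_id plus gel.channel columns")
    spot_ids = df.iloc[:, 0].tolist()
    by_gel: dict[str, dict[str, str]] = {}
    gel_order: list[str] = []
    for col in df.columns[1:]:
        gel, dot, channel = str(col).rpartition(".")
        if not dot or channel not in CHANNELS:
            raise FormatError(
                f"{path}: column {col!r} does not follow '<gel>.sample'/'<gel>.ips'"
            )
        if gel not in by_gel:
            by_gel[gel] = {}
            gel_order.append(gel)
        by_gel[gel][channel] = col
    for gel in gel_order:
        for channel in CHANNELS:
            if channel not in by_gel[gel]:
                raise FormatError(f"{path}: gel {gel!r} is missing its {channel} column")
    data = {}
    for channel in CHANNELS:
        sub = df[[by_gel[g][channel] for g in gel_order]]
        values = sub.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        nan = np.isnan(values) & ~sub.isna().to_numpy()
        if nan.any() or sub.isna().to_numpy().any():
            bad = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"{path}: missing or non-numeric value at spot "
                f"{spot_ids[bad[0]]!r}, column {sub.columns[bad[1]]!r}"
            )
        data[channel] = values
    return SpotMatrix(spot_ids, gel_order, data["sample"], data["ips"])


def write_spot_table(matrix: SpotMatrix, path, sep: Optional[str] = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, sep)
    cols: dict[str, object] = {"spot_id": matrix.spot_ids}
    for j, gel in enumerate(matrix.gel_ids):
        cols[f"{gel}.sample"] = matrix.sample[:, j]
        cols[f"{gel}.ips"] = matrix.ips[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_design(path, sep: Optional[str] = None) -> DesignTable:
    """Read a two-column ``gel_id``/``group`` table (labels case-insensitive)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gel_id, group")
    gels = df.iloc[:, 0].tolist()
    _check_unique(gels, "gel_id")
    return DesignTable({g: Group.parse(v) for g, v in zip(gels, df.iloc[:, 1])})


def write_design(design: DesignTable, path, sep: Optional[str] = None) -> None:
    path = Path(path)
    pd.DataFrame(
        {"gel_id": design.gel_ids, "group": [design.groups[g].value for g in design.gel_ids]}
    ).to_csv(path, sep=_infer_sep(path, sep), index=False)


def read_annotation(path, sep: Optional[str] = None) -> AnnotationTable:
    """Read a four-column ``spot_id``/``accession``/``gene``/``spot_class`` table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, keep_default_na=False)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected columns spot_id, accession, gene, spot_class")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpotAnnotation(
                spot_id=str(row.iloc[0]),
                accession=row.iloc[1] or None,
                gene=row.iloc[2] or None,
                spot_class=SpotClass.parse(row.iloc[3]),
            )
        )
    return AnnotationTable(records)


def write_annotation(annotation: AnnotationTable, path, sep: Optional[str] = None) -> None:
    path = Path(path)
    annotation.to_frame().to_csv(path, sep=_infer_sep(path, sep), index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set_id, description, members...)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, name and >=1 member")
        sets.append(GeneSet(set_id=fields[0], name=fields[1], members=set(fields[2:])))
    _check_unique([s.set_id for s in sets], "set_id")
    return sets


def write_gmt(genesets: Iterable[GeneSet], path) -> None:
    lines = [
        "\t".join([s.set_id, s.name, *sorted(s.members)]) for s in genesets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_directions(path, genesets: Sequence[GeneSet], sep: Optional[str] = None) -> None:
    """Attach expected directions from a sidecar ``set_id``/``gene``/``direction`` table.

    Modifies ``genesets`` in place.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    by_id = {s.set_id: s for s in genesets}
    for _, row in df.iterrows():
        set_id, gene, direction = str(row.iloc[0]), str(row.iloc[1]), str(row.iloc[2]).lower()
        if set_id not in by_id:
            raise JoinError(f"{path}: direction for unknown set {set_id!r}")
        gs = by_id[set_id]
        if gene not in gs.members:
            raise ValidationError(f"{path}: {gene!r} is not a member of {set_id!r}")
        if direction not in ("up", "down"):
            raise ValidationError(f"{path}: direction must be up/down, got {direction!r}")
        gs.expected_direction[gene] = direction
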