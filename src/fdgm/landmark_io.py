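"""Reading, writing and validating TPS landmark files.

The TPS dialect handled here is the plain-text interchange format of the
tps software family: each record starts with an ``LM=<N>`` line, followed
by ``N`` lines of whitespace-separated x/y coordinates, optionally
followed by ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  Only 2D records
are accepted; ``LM3=`` (3D) records and ``CURVES``/``POINTS`` outline
blocks are rejected because this toolkit treats every digitised point as
an ordinary landmark in digitisation order.

Landmark ordering is sacrosanct: the digitisation order defines the
functional domain downstream, so coordinates are never permuted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VIEWS = ("dorsal", "jaw", "lateral", "other")

TYPE_I = "typeI"
TYPE_III = "typeIII"


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when landmark data violates a structural invariant."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Unique identifier within a replicate set.
    coords : ndarray of shape (N, 2)
        Landmark coordinates in digitisation order, image units.
    species_label : str
        Class label (e.g. species name); empty string if unknown.
    view : str
        One of ``dorsal``, ``jaw``, ``lateral``, ``other``.
    landmark_types : sequence of str
        Per-landmark flag, ``typeI`` (homologous point) or ``typeIII``
        (semilandmark).  Annotation only; no differential treatment.
    scale : float or None
        The TPS SCALE factor if present.  Not applied to coordinates
        unless requested at read time.
    """

    specimen_id: str
    coords: np.ndarray
    species_label: str = ""
    view: str = "other"
    landmark_types: Sequence[str] = field(default_factory=list)
    scale: float | None = None
    image: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"coords must be (N, 2), got {self.coords.shape}"
            )
        n = self.coords.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 landmarks, got {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )
        if not self.landmark_types:
            self.landmark_types = [TYPE_I] * n
        if len(self.landmark_types) != n:
            raise ValidationError(
                f"landmark_types length {len(self.landmark_types)} != N={n}"
            )
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValidationError("SCALE must be positive")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A sample of landmark configurations sharing one view and landmark set."""

    configurations: list[LandmarkConfiguration]
    view: str = "other"

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValidationError("dataset must contain at least one configuration")
        n_landmarks = {c.n_landmarks for c in self.configurations}
        if len(n_landmarks) > 1:
            raise ValidationError(
                f"inconsistent landmark counts across configurations: {sorted(n_landmarks)}"
            )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def n_landmarks(self) -> int:
        return self.configurations[0].n_landmarks

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def labels(self) -> list[str]:
        return [c.species_label for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, N, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def by_id(self) -> dict[str, LandmarkConfiguration]:
        return {c.specimen_id: c for c in self.configurations}


# ---------------------------------------------------------------------------
# TPS parsing


def _finish_record(
    record_index: int,
    n_expected: int | None,
    coord_lines: list[str],
    meta: dict[str, str],
    species_label: str,
    view: str,
    apply_scale: bool,
) -> LandmarkConfiguration:
    if n_expected is None:
        raise TPSParseError(f"record {record_index}: missing LM= line")
    if len(coord_lines) != n_expected:
        raise TPSParseError(
            f"record {record_index}: LM={n_expected} but "
            f"{len(coord_lines)} coordinate lines present"
        )
    coords = np.empty((n_expected, 2))
    for i, line in enumerate(coord_lines):
        parts = line.split()
        if len(parts) != 2:
            raise TPSParseError(
                f"record {record_index}: expected 'x y' on coordinate "
                f"line {i + 1}, got {line!r}"
            )
        try:
            coords[i] = [float(parts[0]), float(parts[1])]
        except ValueError as exc:
            raise TPSParseError(
                f"record {record_index}: non-numeric coordinate on "
                f"line {i + 1}: {line!r}"
            ) from exc
    scale = None
    if "SCALE" in meta:
        try:
            scale = float(meta["SCALE"])
        except ValueError as exc:
            raise TPSParseError(
                f"record {record_index}: non-numeric SCALE {meta['SCALE']!r}"
            ) from exc
        if apply_scale:
            coords = coords * scale
    specimen_id = meta.get("ID", f"record_{record_index}")
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        coords=coords,
        species_label=species_label,
        view=view,
        scale=scale,
        image=meta.get("IMAGE"),
    )


def read_tps(
    path: str | Path,
    species_label: str = "",
    view: str = "other",
    apply_scale: bool = False,
) -> LandmarkDataset:
    """Read a 2D TPS landmark file into a :class:`LandmarkDataset`.

    Parameters
    ----------
    path : path
        TPS file to read.
    species_label : str
        Class label attached to every record in the file.
    view : str
        Anatomical view of the configurations.
    apply_scale : bool
        If True, multiply coordinates by the record's SCALE factor.
        Off by default: downstream Procrustes alignment removes size, so
        physical scaling is irrelevant to shape analysis.
    """
    path = Path(path)
    text = path.read_text()
    records: list[LandmarkConfiguration] = []
    n_expected: int | None = None
    coord_lines: list[str] = []
    meta: dict[str, str] = {}
    in_record = False
    record_index = 0

    def flush() -> None:
        nonlocal in_record, n_expected, coord_lines, meta
        if in_record:
            records.append(
                _finish_record(
                    record_index, n_expected, coord_lines, meta,
                    species_label, view, apply_scale,
                )
            )
            in_record = False
            n_expected = None
            coord_lines = []
            meta = {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            raise TPSParseError(
                "3D records (LM3=) are not supported; this toolkit is strictly 2D"
            )
        if upper.startswith(("CURVES=", "POINTS=", "OUTLINES=")):
            raise TPSParseError(
                f"{line.split('=')[0]} blocks are not supported; store "
                "semilandmarks as ordinary landmarks"
            )
        if upper.startswith("LM="):
            flush()
            record_index += 1
            in_record = True
            try:
                n_expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSParseError(
                    f"record {record_index}: malformed LM= line {line!r}"
                ) from exc
            continue
        if "=" in line and not line.split("=", 1)[0].strip().lstrip("-").replace(".", "").isdigit():
            key, value = line.split("=", 1)
            meta[key.strip().upper()] = value.strip()
            continue
        if not in_record:
            raise TPSParseError(f"coordinate line outside any record: {line!r}")
        coord_lines.append(line)
    flush()

    if not records:
        raise TPSParseError(f"no TPS records found in {path}")
    return LandmarkDataset(configurations=records, view=view)


def write_tps(dataset: LandmarkDataset, path: str | Path, decimals: int = 6) -> None:
    """Write a dataset in the same TPS dialect that :func:`read_tps` accepts."""
    path = Path(path)
    lines: list[str] = []
    fmt = f"{{:.{decimals}f}} {{:.{decimals}f}}"
    for config in dataset.configurations:
        lines.append(f"LM={config.n_landmarks}")
        for x, y in config.coords:
            lines.append(fmt.format(x, y))
        if config.image is not None:
            lines.append(f"IMAGE={config.image}")
        lines.append(f"ID={config.specimen_id}")
        if config.scale is not None:
            lines.append(f"SCALE={config.scale}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Replicate handling


def average_replicates(replicates: Sequence[LandmarkDataset]) -> LandmarkDataset:
    """Average R digitisation replicates into one configuration per specimen.

    Landmarks are digitised several times per specimen to quantify
    observer error; the arithmetic per-landmark mean over replicates is
    used for analysis.  Specimens are matched by ``specimen_id`` across
    replicate sets, so replicate ordering within each set is irrelevant.
    Metadata (labels, view, scale) is copied from the first replicate set.
    """
    if len(replicates) < 1:
        raise ValidationError("need at least one replicate set")
    first = replicates[0]
    ref_ids = set(first.specimen_ids)
    for r, rep in enumerate(replicates[1:], start=2):
        if rep.n_landmarks != first.n_landmarks:
            raise ValidationError(
                f"replicate set {r}: landmark count {rep.n_landmarks} != "
                f"{first.n_landmarks}"
            )
        if rep.view != first.view:
            raise ValidationError(
                f"replicate set {r}: view {rep.view!r} != {first.view!r}"
            )
        missing = ref_ids.symmetric_difference(rep.specimen_ids)
        if missing:
            raise ValidationError(
                f"replicate set {r}: specimen ids not shared across all "
                f"sets: {sorted(missing)}"
            )
    maps = [rep.by_id() for rep in replicates]
    averaged = []
    for config in first.configurations:
        stack = np.stack([m[config.specimen_id].coords for m in maps])
        # Sum in a canonical (sorted) order so the result is exactly
        # invariant to replicate ordering, and return the common value
        # exactly where all replicates agree.
        ordered = np.sort(stack, axis=0)
        mean = ordered.sum(axis=0) / len(replicates)
        mean = np.where(ordered[0] == ordered[-1], ordered[0], mean)
        averaged.append(replace(config, coords=mean))
    return LandmarkDataset(configurations=averaged, view=first.view)


def replicate_deviation(
    replicates: Sequence[LandmarkDataset],
    averaged: LandmarkDataset | None = None,
) -> np.ndarray:
    """Mean per-landmark deviation of each replicate from the average.

    Returns an array of length R; entry r is the mean Euclidean
    distance between replicate r's landmarks and the averaged landmarks,
    over all specimens and landmarks.  Zero for every entry iff the
    replicates are identical.
    """
    if averaged is None:
        averaged = average_replicates(replicates)
    avg_map = averaged.by_id()
    out = np.empty(len(replicates))
    for r, rep in enumerate(replicates):
        devs = [
            np.linalg.norm(c.coords - avg_map[c.specimen_id].coords, axis=1)
            for c in rep.configurations
        ]
        out[r] = float(np.mean(np.concatenate(devs)))
    return out


# ---------------------------------------------------------------------------
# Dataset manifest

MANIFEST_COLUMNS = ("specimen_id", "species_label", "view", "tps_path", "replicate_index")


def read_manifest(path: str | Path) -> dict[str, list[LandmarkDataset]]:
    """Read a manifest CSV and load the TPS files it references.

    The manifest has columns ``specimen_id, species_label, view,
    tps_path, replicate_index``; one row per (specimen, replicate).  TPS
    paths are resolved relative to the manifest's directory.  Returns a
    mapping view -> list of replicate LandmarkDataset (ordered by
    replicate index).
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        rows = list(reader)
    out: dict[str, list[LandmarkDataset]] = {}
    # Group rows by (view, replicate, tps_path) so one file can carry many records.
    by_view: dict[str, dict[int, list[dict[str, str]]]] = {}
    for row in rows:
        by_view.setdefault(row["view"], {}).setdefault(
            int(row["replicate_index"]), []
        ).append(row)
    for view, reps in by_view.items():
        datasets = []
        for rep_idx in sorted(reps):
            configs: list[LandmarkConfiguration] = []
            seen_files: dict[str, LandmarkDataset] = {}
            for row in reps[rep_idx]:
                tps_path = (path.parent / row["tps_path"]).resolve()
                key = str(tps_path)
                if key not in seen_files:
                    seen_files[key] = read_tps(tps_path, view=view)
                file_map = seen_files[key].by_id()
                if row["specimen_id"] not in file_map:
                    raise ValidationError(
                        f"specimen {row['specimen_id']!r} not found in {tps_path}"
                    )
                config = file_map[row["specimen_id"]]
                configs.append(
                    replace(config, species_label=row["species_label"], view=view)
                )
            datasets.append(LandmarkDataset(configurations=configs, view=view))
        out[view] = datasets
    return out


def write_manifest(
    path: str | Path,
    entries: Iterable[tuple[str, str, str, str, int]],
) -> None:
    """Write a manifest CSV from (specimen_id, label, view, tps_path, replicate) tuples."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for entry in entries:
            writer.writerow(entry)
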