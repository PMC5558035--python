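"""Reading, writing and validating connectomes, parcellations and cohort tables.

A *parcellation* fixes the node set of every matrix in an analysis: an
ordered list of grey-matter regions, each carrying a hemisphere label and
optional functional-network flags (language-specific vs domain-general).
A *connectome* is a symmetric, nonnegative, zero-diagonal weighted adjacency
matrix over those regions; weights are streamline-density-like quantities in
arbitrary units and arrive precomputed (tractography itself is upstream of
this package).  Cohorts bundle per-subject connectomes with behavior scores
(WAB-AQ and its four subscores, each on 0-100) and per-region damage
fractions.

All on-disk formats are delimited text (comma or tab, auto-detected) with
labelled header rows so fixtures stay human-inspectable.  Writers use 17
significant digits, which round-trips float64 values exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Region",
    "Parcellation",
    "Connectome",
    "SubjectRecord",
    "CohortData",
    "ROI_TAGS",
    "SUBSCORE_NAMES",
    "load_parcellation",
    "write_parcellation",
    "default_parcellation",
    "load_connectome",
    "write_connectome",
    "hemisphere_submatrix",
    "load_cohort",
    "write_cohort",
]

HEMISPHERES = ("L", "R")

#: Anatomical tags used to locate the classical language ROIs and the
#: language-specific / domain-general subnetworks in a parcellation.
ROI_TAGS = frozenset(
    {
        "pars_triangularis",
        "pars_opercularis",
        "STG",
        "STG_pole",
        "MTG",
        "PMTG",
        "PITG",
        "AG",
        "MFG_post",
        "SFG_post",
        "MFG_DPFC",
        "IFG_orbitalis",
        "PrCG",
        "SPG",
        "SMG",
        "PCC",
        "insula",
        "none",
    }
)

SUBSCORE_NAMES = ("comprehension", "fluency", "naming", "repetition")

#: Relative tolerance for accepting (and silently symmetrizing) asymmetric
#: input matrices; larger asymmetries are treated as data errors.
ASYMMETRY_RTOL = 1e-9

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Parcellation


@dataclass(frozen=True)
class Region:
    region_id: str
    name: str
    hemisphere: str
    language_specific: bool = False
    domain_general: bool = False
    roi_tag: str = "none"

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise FormatError(
                f"region {self.region_id!r}: hemisphere must be one of "
                f"{HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.roi_tag not in ROI_TAGS:
            raise FormatError(
                f"region {self.region_id!r}: unknown roi_tag {self.roi_tag!r}"
            )
        if self.language_specific and self.domain_general:
            raise FormatError(
                f"region {self.region_id!r}: language_specific and "
                "domain_general are mutually exclusive"
            )


@dataclass(frozen=True)
class Parcellation:
    """Ordered region metadata anchoring all matrices of an analysis."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate region_id(s): {dupes}")

    # -- basic views -------------------------------------------------------

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region_id {region_id!r}") from None

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        return np.array(
            [i for i, r in enumerate(self.regions) if r.hemisphere == hemisphere],
            dtype=np.intp,
        )

    def subset(self, indices: Sequence[int]) -> "Parcellation":
        return Parcellation(tuple(self.regions[int(i)] for i in indices))

    @property
    def language_specific_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions if r.language_specific)

    @property
    def domain_general_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions if r.domain_general)

    def find_roi(self, roi_tag: str, hemisphere: str = "L") -> str | None:
        """region_id of the tagged ROI in the given hemisphere, or None."""
        for r in self.regions:
            if r.roi_tag == roi_tag and r.hemisphere == hemisphere:
                return r.region_id
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "language_specific": [int(r.language_specific) for r in self.regions],
                "domain_general": [int(r.domain_general) for r in self.regions],
                "roi_tag": [r.roi_tag for r in self.regions],
            }
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma vs tab."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


_BOOL_MAP = {"1": True, "0": False, "true": True, "false": False, "": False}


def load_parcellation(path: str | Path) -> Parcellation:
    """Load region metadata from a delimited text file.

    Required columns: region_id, name, hemisphere, language_specific,
    domain_general, roi_tag.  Region order is file order.
    """
    df = _read_table(path)
    required = {
        "region_id",
        "name",
        "hemisphere",
        "language_specific",
        "domain_general",
        "roi_tag",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    def as_bool(v: str, col: str) -> bool:
        key = v.strip().lower()
        if key not in _BOOL_MAP:
            raise FormatError(f"{path}: bad boolean {v!r} in column {col}")
        return _BOOL_MAP[key]

    regions = tuple(
        Region(
            region_id=row["region_id"].strip(),
            name=row["name"].strip(),
            hemisphere=row["hemisphere"].strip(),
            language_specific=as_bool(row["language_specific"], "language_specific"),
            domain_general=as_bool(row["domain_general"], "domain_general"),
            roi_tag=row["roi_tag"].strip() or "none",
        )
        for _, row in df.iterrows()
    )
    return Parcellation(regions)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    parc.to_frame().to_csv(path, index=False)


def default_parcellation() -> Parcellation:
    """The bundled 114-region parcellation (57 per hemisphere).

    Mirrors the grey-matter subset of an adult whole-brain atlas at the scale
    used for hemispheric analyses, with 9 language-specific and 8
    domain-general left-hemisphere regions flagged.
    """
    from importlib.resources import files

    with files("connfrag.data").joinpath("default_parcellation.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    regions = tuple(
        Region(
            region_id=row["region_id"],
            name=row["name"],
            hemisphere=row["hemisphere"],
            language_specific=row["language_specific"] == "1",
            domain_general=row["domain_general"] == "1",
            roi_tag=row["roi_tag"] or "none",
        )
        for _, row in df.iterrows()
    )
    return Parcellation(regions)


# ---------------------------------------------------------------------------
# Connectome


@dataclass
class Connectome:
    """Symmetric nonnegative weighted adjacency over an ordered region set.

    ``weights[i, j]`` is the connection weight between ``region_ids[i]`` and
    ``region_ids[j]``; the diagonal is zero.  ``total_weight`` counts every
    undirected edge twice (the sum of the full matrix), the convention under
    which the modularity decomposition's edge fractions add to one.
    """

    region_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.region_ids = tuple(self.region_ids)
        w = np.asarray(self.weights, dtype=np.float64)
        n = len(self.region_ids)
        if w.shape != (n, n):
            raise FormatError(
                f"weights shape {w.shape} does not match {n} region ids"
            )
        if not np.all(np.isfinite(w)):
            raise FormatError("weights must be finite")
        if (w < 0).any():
            raise FormatError("weights must be nonnegative")
        scale = w.max() if w.size and w.max() > 0 else 1.0
        if np.abs(w - w.T).max() > ASYMMETRY_RTOL * scale:
            raise FormatError(
                "weights asymmetric beyond tolerance "
                f"(rtol={ASYMMETRY_RTOL:g}); refusing to symmetrize"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = np.ascontiguousarray(w)

    def __len__(self) -> int:
        return len(self.region_ids)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region_id {region_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.region_ids), columns=list(self.region_ids)
        )


def load_connectome(path: str | Path, parc: Parcellation | None = None) -> Connectome:
    """Load a labelled square weight matrix.

    Row/column labels must match (and are reordered to) the parcellation's
    region order when ``parc`` is given.  Input asymmetric within the
    relative tolerance is symmetrized as (M + Mᵀ)/2; a nonzero diagonal is
    forced to zero with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is not square {df.shape}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise FormatError(f"{path}: row labels differ from column labels")
    if parc is not None:
        expected = list(parc.region_ids)
        if sorted(rows) != sorted(expected):
            raise FormatError(
                f"{path}: matrix labels do not match parcellation region_ids"
            )
        df = df.loc[expected, expected]
        rows = expected
    w = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise FormatError(f"{path}: non-finite weights")
    if (w < 0).any():
        raise FormatError(f"{path}: negative weights")
    if np.abs(np.diag(w)).max(initial=0.0) > 0:
        logger.warning("%s: nonzero diagonal forced to 0", path)
    return Connectome(tuple(rows), w)


def write_connectome(c: Connectome, path: str | Path) -> None:
    c.to_frame().to_csv(path, float_format=_FLOAT_FMT)


def hemisphere_submatrix(c: Connectome, parc: Parcellation, hemisphere: str) -> Connectome:
    """Extract one hemisphere's intra-hemispheric connectome.

    Interhemispheric (commissural) edges are discarded: per-hemisphere
    community structure is defined on hemisphere-local connectivity only.
    """
    if tuple(parc.region_ids) != tuple(c.region_ids):
        raise ValueError("connectome region order does not match parcellation")
    idx = parc.hemisphere_indices(hemisphere)
    if len(idx) < 2:
        raise ValueError(
            f"hemisphere {hemisphere!r} has {len(idx)} region(s); need at least 2"
        )
    sub = c.weights[np.ix_(idx, idx)]
    ids = tuple(c.region_ids[int(i)] for i in idx)
    return Connectome(ids, sub)


# ---------------------------------------------------------------------------
# Subjects and cohorts


@dataclass
class SubjectRecord:
    """One subject: behavior, regional damage fractions and whole connectome."""

    subject_id: str
    wab_aq: float
    subscores: dict[str, float]
    damage: dict[str, float]
    grey_damage_total: float
    white_damage_total: float
    lesion_volume_cm3: float
    connectome: Connectome

    def __post_init__(self) -> None:
        if not 0.0 <= self.wab_aq <= 100.0:
            raise FormatError(
                f"subject {self.subject_id}: wab_aq {self.wab_aq} outside [0, 100]"
            )
        for name in SUBSCORE_NAMES:
            if name not in self.subscores:
                raise FormatError(
                    f"subject {self.subject_id}: missing subscore {name!r}"
                )
        for rid, d in self.damage.items():
            if not 0.0 <= d <= 1.0:
                raise FormatError(
                    f"subject {self.subject_id}: damage[{rid}] = {d} outside [0, 1]"
                )
        for label, v in (
            ("grey_damage_total", self.grey_damage_total),
            ("white_damage_total", self.white_damage_total),
        ):
            if not 0.0 <= v <= 1.0:
                raise FormatError(
                    f"subject {self.subject_id}: {label} = {v} outside [0, 1]"
                )
        if self.lesion_volume_cm3 < 0:
            raise FormatError(
                f"subject {self.subject_id}: negative lesion volume"
            )

    def damage_vector(self, parc: Parcellation) -> np.ndarray:
        return np.array(
            [self.damage.get(rid, 0.0) for rid in parc.region_ids], dtype=float
        )


@dataclass
class CohortData:
    """A parcellation-aligned cohort of subjects, with optional ground truth.

    ``ground_truth`` is populated only for synthetic cohorts and records the
    generator's injected quantities (per-subject lesion extent, internal
    fragmentation index, behavior-model coefficients, seed).
    """

    parcellation: Parcellation
    subjects: list[SubjectRecord]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject_id in cohort")
        expected = tuple(self.parcellation.region_ids)
        for s in self.subjects:
            if tuple(s.connectome.region_ids) != expected:
                raise FormatError(
                    f"subject {s.subject_id}: connectome regions do not match "
                    "the cohort parcellation"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"unknown subject_id {subject_id!r}")

    def score_series(self, score_name: str) -> pd.Series:
        """Behavior score per subject (``wab_aq`` or a subscore name)."""
        if score_name == "wab_aq":
            vals = {s.subject_id: s.wab_aq for s in self.subjects}
        else:
            if score_name not in SUBSCORE_NAMES:
                raise ValueError(
                    f"unknown score {score_name!r}; expected 'wab_aq' or one of "
                    f"{SUBSCORE_NAMES}"
                )
            vals = {s.subject_id: s.subscores[score_name] for s in self.subjects}
        return pd.Series(vals, name=score_name)


_MANIFEST_COLUMNS = [
    "subject_id",
    "wab_aq",
    "comprehension",
    "fluency",
    "naming",
    "repetition",
    "grey_damage_total",
    "white_damage_total",
    "lesion_volume_cm3",
    "damage_path",
    "connectome_path",
]


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Write a cohort directory: manifest, parcellation, per-subject tables.

    Layout::

        out_dir/
          manifest.csv        one row per subject, paths relative to out_dir
          parcellation.csv
          ground_truth.json   synthetic cohorts only
          subjects/<id>_connectome.csv
          subjects/<id>_damage.csv
    """
    out_dir = Path(out_dir)
    (out_dir / "subjects").mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, out_dir / "parcellation.csv")
    rows = []
    for s in cohort.subjects:
        conn_rel = f"subjects/{s.subject_id}_connectome.csv"
        dmg_rel = f"subjects/{s.subject_id}_damage.csv"
        write_connectome(s.connectome, out_dir / conn_rel)
        pd.DataFrame(
            {
                "region_id": list(cohort.parcellation.region_ids),
                "damage": [
                    s.damage.get(rid, 0.0) for rid in cohort.parcellation.region_ids
                ],
            }
        ).to_csv(out_dir / dmg_rel, index=False, float_format=_FLOAT_FMT)
        rows.append(
            {
                "subject_id": s.subject_id,
                "wab_aq": s.wab_aq,
                **{k: s.subscores[k] for k in SUBSCORE_NAMES},
                "grey_damage_total": s.grey_damage_total,
                "white_damage_total": s.white_damage_total,
                "lesion_volume_cm3": s.lesion_volume_cm3,
                "damage_path": dmg_rel,
                "connectome_path": conn_rel,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        out_dir / "manifest.csv", index=False, float_format=_FLOAT_FMT
    )
    if cohort.ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
    return out_dir


def load_cohort(manifest_path: str | Path) -> CohortData:
    """Load a cohort from a manifest file or a cohort directory."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    base = manifest_path.parent
    parc = load_parcellation(base / "parcellation.csv")
    df = _read_table(manifest_path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{manifest_path}: missing columns {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        try:
            conn = load_connectome(base / row["connectome_path"], parc)
            dmg_df = _read_table(base / row["damage_path"])
            damage = {
                r["region_id"]: float(r["damage"]) for _, r in dmg_df.iterrows()
            }
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    wab_aq=float(row["wab_aq"]),
                    subscores={k: float(row[k]) for k in SUBSCORE_NAMES},
                    damage=damage,
                    grey_damage_total=float(row["grey_damage_total"]),
                    white_damage_total=float(row["white_damage_total"]),
                    lesion_volume_cm3=float(row["lesion_volume_cm3"]),
                    connectome=conn,
                )
            )
        except (OSError, FormatError, ValueError) as exc:
            raise FormatError(f"subject {sid}: {exc}") from exc
    gt_path = base / "ground_truth.json"
    ground_truth = None
    if gt_path.exists():
        with open(gt_path) as fh:
            ground_truth = json.load(fh)
    return CohortData(parcellation=parc, subjects=subjects, ground_truth=ground_truth)
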