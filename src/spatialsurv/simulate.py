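"""Synthetic spatial survival cohorts with planted ground truth.

A cohort is generated in three layers:

1. **Geometry** — per patient, community centers are sampled uniformly in
   a square bounding box and cell positions are isotropic Gaussians around
   the centers, so the radius graph recovers the communities.
2. **Composition** — each patient carries a latent subtype; phenotypes are
   drawn from the subtype's multinomial mixture, and clinical covariates
   (ER/PR/HER2, grade) are sampled conditionally on the subtype so
   molecular-subtype cross-tabulations are non-degenerate.
3. **Survival** — death times are exponential with proportional hazards:
   rate = ``baseline_hazard * exp(lp)`` where the linear predictor ``lp``
   applies the planted ``effect_vector`` to the patient's *actual* feature
   values (z-scored across the cohort so coefficients are per standard
   deviation).  Censoring is uniform on ``(0, censoring_window]``.

The returned ground truth (latent subtypes, effects, linear predictor)
supports recovery tests: feature selection should enrich for planted
effects and consensus clustering should recover the planted subtype count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .features import (
    FeatureMatrix,
    PatientImage,
    assemble_features,
    ccis_feature_name,
    density_feature_name,
)
from .palette import PhenotypePalette, default_palette
from .survival import SurvivalOutcome

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "default_phenotype_mixtures",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "simulate_expression_pair",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Lengths are μm, times months.  ``phenotype_mixtures`` is one
    multinomial over the palette per latent subtype (rows sum to 1);
    ``effect_vector`` maps feature names (``density|…`` / ``ccis|…|…``) to
    log-hazard coefficients per standard deviation of the feature.
    """

    n_patients: int = 100
    n_latent_subtypes: int = 4
    communities_per_patient: tuple[int, int] = (4, 8)
    cells_per_community: tuple[int, int] = (30, 60)
    community_spread: float = 12.0
    neighbor_radius: float = 4.0
    bounding_box: float = 1000.0
    phenotype_mixtures: np.ndarray | None = None
    effect_vector: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    censoring_window: float = 240.0
    seed: int = 0

    def validate(self, palette: PhenotypePalette) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_window <= 0:
            raise ValueError("censoring_window must be positive")
        if self.community_spread <= 0:
            raise ValueError("community_spread must be positive")
        mix = self.mixtures(palette)
        if mix.shape != (self.n_latent_subtypes, len(palette)):
            raise ValueError(
                "phenotype_mixtures must have one row per latent subtype and "
                "one column per phenotype"
            )
        if (mix < 0).any() or mix.sum() == 0:
            raise ValueError("phenotype mixtures must be non-negative and non-empty")
        if not np.allclose(mix.sum(axis=1), 1.0):
            raise ValueError("each phenotype mixture must sum to 1")

    def mixtures(self, palette: PhenotypePalette) -> np.ndarray:
        if self.phenotype_mixtures is None:
            return default_phenotype_mixtures(self.n_latent_subtypes, palette)
        return np.asarray(self.phenotype_mixtures, dtype=float)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    subtype_of: dict[str, int]
    true_effects: dict[str, float]
    true_linear_predictor: pd.Series


class Cohort(NamedTuple):
    images: list[PatientImage]
    clinical: pd.DataFrame
    outcome: SurvivalOutcome
    ground_truth: GroundTruth
    palette: PhenotypePalette


def default_phenotype_mixtures(
    n_subtypes: int, palette: PhenotypePalette
) -> np.ndarray:
    """Deterministic per-subtype multinomials over the palette.

    Every phenotype gets a uniform base weight; each subtype up-weights a
    signature trio (one immune, one stromal, two epithelial phenotypes,
    cycling through the palette) eight-fold, giving subtypes distinct but
    overlapping compositions.
    """
    k = len(palette)
    immune = [palette.index(p) for p in palette.members("immune")]
    stromal = [palette.index(p) for p in palette.members("stromal")]
    epithelial = [palette.index(p) for p in palette.members("epithelial")]
    mix = np.ones((n_subtypes, k))
    for s in range(n_subtypes):
        boost = []
        if immune:
            boost.append(immune[s % len(immune)])
        if stromal:
            boost.append(stromal[s % len(stromal)])
        if epithelial:
            boost.append(epithelial[(2 * s) % len(epithelial)])
            boost.append(epithelial[(2 * s + 1) % len(epithelial)])
        mix[s, boost] += 8.0
    return mix / mix.sum(axis=1, keepdims=True)


# Per-latent-subtype clinical profiles: probabilities of ER/PR/HER2
# positivity and of tumor grades 1..3.  Profiles cycle so that latent
# subtypes map onto distinct molecular-subtype propensities.
_CLINICAL_PROFILES = (
    {"er": 0.85, "pr": 0.75, "her2": 0.10, "grade": (0.4, 0.45, 0.15)},  # luminal-A-like
    {"er": 0.80, "pr": 0.55, "her2": 0.75, "grade": (0.15, 0.45, 0.40)},  # luminal-B-like
    {"er": 0.10, "pr": 0.10, "her2": 0.08, "grade": (0.05, 0.30, 0.65)},  # TNBC-like
    {"er": 0.12, "pr": 0.12, "her2": 0.85, "grade": (0.10, 0.40, 0.50)},  # HER2-like
)


def generate_cohort(
    config: SimConfig, palette: PhenotypePalette | None = None
) -> Cohort:
    """Generate a synthetic cohort with planted spatial/compositional/survival structure.

    Identical configs (including seed) produce identical cohorts.
    """
    palette = palette or default_palette()
    config.validate(palette)
    rng = np.random.default_rng(config.seed)
    mixtures = config.mixtures(palette)
    box = config.bounding_box
    names = list(palette.names)

    images: list[PatientImage] = []
    clin_rows = []
    subtype_of: dict[str, int] = {}
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        subtype = int(rng.integers(config.n_latent_subtypes))
        subtype_of[pid] = subtype
        lo, hi = config.communities_per_patient
        n_comm = int(rng.integers(lo, hi + 1))
        xs, ys, phenos = [], [], []
        for _ in range(n_comm):
            center = rng.uniform(0, box, size=2)
            lo_c, hi_c = config.cells_per_community
            n_cells = int(rng.integers(lo_c, hi_c + 1))
            pos = rng.normal(center, config.community_spread, size=(n_cells, 2))
            pos = np.clip(pos, 0, box)
            xs.extend(pos[:, 0])
            ys.extend(pos[:, 1])
            phenos.extend(rng.choice(names, size=n_cells, p=mixtures[subtype]))
        cells = pd.DataFrame(
            {
                "cell_id": [f"{pid}_c{j}" for j in range(len(xs))],
                "x_um": xs,
                "y_um": ys,
                "phenotype": phenos,
            }
        )
        images.append(
            PatientImage(
                patient_id=pid,
                cells=cells,
                area_um2=box * box,
                neighbor_radius=config.neighbor_radius,
            )
        )
        profile = _CLINICAL_PROFILES[subtype % len(_CLINICAL_PROFILES)]
        clin_rows.append(
            {
                "patient_id": pid,
                "er": int(rng.random() < profile["er"]),
                "pr": int(rng.random() < profile["pr"]),
                "her2": int(rng.random() < profile["her2"]),
                "grade": int(rng.choice((1, 2, 3), p=profile["grade"])),
            }
        )
    clinical = pd.DataFrame(clin_rows)

    lp = _linear_predictor(images, palette, config)
    rate = config.baseline_hazard * np.exp(lp.to_numpy())
    death = rng.exponential(1.0 / rate)
    censor = rng.uniform(0, config.censoring_window, size=len(death))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    time = np.maximum(time, 1e-6)  # guard against zero times
    outcome = SurvivalOutcome([im.patient_id for im in images], time, event)
    truth = GroundTruth(
        subtype_of=subtype_of,
        true_effects=dict(config.effect_vector),
        true_linear_predictor=lp,
    )
    return Cohort(images, clinical, outcome, truth, palette)


def _linear_predictor(
    images: list[PatientImage], palette: PhenotypePalette, config: SimConfig
) -> pd.Series:
    pids = [im.patient_id for im in images]
    if not config.effect_vector:
        return pd.Series(np.zeros(len(images)), index=pids, name="lp")
    matrix = assemble_features(images, palette)
    lp = np.zeros(len(images))
    for name, beta in config.effect_vector.items():
        if name not in matrix.values.columns:
            raise KeyError(f"effect_vector names unknown feature {name!r}")
        col = matrix.values[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp += beta * z
    return pd.Series(lp, index=pids, name="lp")


# ---------------------------------------------------------------------------
# cohort I/O


_ER_MAP = {"pos": 1, "neg": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def _encode_receptor(v: int) -> str:
    return "pos" if int(v) == 1 else "neg"


def _parse_receptor(value, column: str, path: Path):
    key = value if isinstance(value, (int, np.integer)) else str(value).strip().lower()
    if key not in _ER_MAP:
        raise ValueError(
            f"{path}: column {column!r} has unparseable receptor status {value!r}"
        )
    return _ER_MAP[key]


def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort as plain-text tables (round-trips with :func:`read_cohort`)."""
    directory = Path(directory)
    (directory / "cells").mkdir(parents=True, exist_ok=True)
    for image in cohort.images:
        image.cells.to_csv(directory / "cells" / f"{image.patient_id}.csv", index=False)
    geometry = pd.DataFrame(
        {
            "patient_id": [im.patient_id for im in cohort.images],
            "area_um2": [im.area_um2 for im in cohort.images],
            "neighbor_radius": [im.neighbor_radius for im in cohort.images],
        }
    )
    geometry.to_csv(directory / "geometry.csv", index=False)
    clin = cohort.clinical.copy()
    for col in ("er", "pr", "her2"):
        clin[col] = clin[col].map(_encode_receptor)
    clin.to_csv(directory / "clinical.csv", index=False)
    cohort.outcome.to_frame().to_csv(directory / "survival.csv", index=False)
    with open(directory / "palette.json", "w") as fh:
        json.dump(
            {"names": list(cohort.palette.names),
             "class_of": dict(cohort.palette.class_of)},
            fh, indent=1,
        )
    truth = cohort.ground_truth
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "subtype_of": truth.subtype_of,
                "true_effects": truth.true_effects,
                "true_linear_predictor": truth.true_linear_predictor.to_dict(),
            },
            fh, indent=1,
        )


def _require_columns(df: pd.DataFrame, cols, path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_cohort(directory) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Clinical receptor statuses may be encoded as ``pos``/``neg`` or 0/1;
    schema violations raise errors naming the offending file and column.
    """
    directory = Path(directory)
    with open(directory / "palette.json") as fh:
        pal = json.load(fh)
    palette = PhenotypePalette(names=tuple(pal["names"]), class_of=pal["class_of"])

    geom_path = directory / "geometry.csv"
    geometry = pd.read_csv(geom_path)
    _require_columns(geometry, ("patient_id", "area_um2", "neighbor_radius"), geom_path)
    images = []
    for row in geometry.itertuples():
        cpath = directory / "cells" / f"{row.patient_id}.csv"
        cells = pd.read_csv(cpath)
        _require_columns(cells, ("cell_id", "x_um", "y_um", "phenotype"), cpath)
        images.append(
            PatientImage(
                patient_id=str(row.patient_id),
                cells=cells,
                area_um2=float(row.area_um2) if np.isfinite(row.area_um2) else None,
                neighbor_radius=float(row.neighbor_radius),
            )
        )

    clin_path = directory / "clinical.csv"
    clinical = pd.read_csv(clin_path)
    _require_columns(clinical, ("patient_id", "er", "pr", "her2", "grade"), clin_path)
    for col in ("er", "pr", "her2"):
        clinical[col] = [
            _parse_receptor(v, col, clin_path) for v in clinical[col]
        ]

    surv_path = directory / "survival.csv"
    surv = pd.read_csv(surv_path)
    _require_columns(surv, ("patient_id", "os_months", "event"), surv_path)
    outcome = SurvivalOutcome(
        [str(p) for p in surv["patient_id"]],
        surv["os_months"].to_numpy(dtype=float),
        surv["event"].to_numpy(dtype=int),
    )

    truth_path = directory / "ground_truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            t = json.load(fh)
        truth = GroundTruth(
            subtype_of={k: int(v) for k, v in t["subtype_of"].items()},
            true_effects={k: float(v) for k, v in t["true_effects"].items()},
            true_linear_predictor=pd.Series(t["true_linear_predictor"], name="lp"),
        )
    else:
        truth = GroundTruth({}, {}, pd.Series(dtype=float, name="lp"))
    return Cohort(images, clinical, outcome, truth, palette)


def write_config(config: SimConfig, path) -> None:
    """Serialize a :class:`SimConfig` to YAML."""
    d = asdict(config)
    if d["phenotype_mixtures"] is not None:
        d["phenotype_mixtures"] = np.asarray(d["phenotype_mixtures"]).tolist()
    d["communities_per_patient"] = list(d["communities_per_patient"])
    d["cells_per_community"] = list(d["cells_per_community"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("phenotype_mixtures") is not None:
        d["phenotype_mixtures"] = np.asarray(d["phenotype_mixtures"], dtype=float)
    d["communities_per_patient"] = tuple(d["communities_per_patient"])
    d["cells_per_community"] = tuple(d["cells_per_community"])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# paired expression cohorts for label-transfer experiments


def simulate_expression_pair(
    n_source: int = 40,
    n_target: int = 120,
    n_markers: int = 30,
    n_groups: int = 2,
    cells_per_patient: int = 50,
    group_shift: float = 2.0,
    hazard_per_group: float = 1.0,
    seed: int = 0,
):
    """Two cohorts sharing latent expression groups, for matcher validation.

    Returns ``(cell_expression, source_groups, target_expression,
    target_groups, target_outcome)``: a cell-level marker table for the
    source cohort (patients share their group's mean profile plus cell
    noise), a patient-level matrix for the target cohort drawn from the
    same group profiles, and target survival whose log-hazard increases by
    ``hazard_per_group`` per group index.
    """
    rng = np.random.default_rng(seed)
    markers = [f"M{j + 1}" for j in range(n_markers)]
    profiles = rng.normal(0, 1, size=(n_groups, n_markers)) * group_shift

    src_groups = rng.integers(n_groups, size=n_source)
    rows = []
    for i in range(n_source):
        pid = f"S{i + 1:03d}"
        base = profiles[src_groups[i]] + rng.normal(0, 0.3, n_markers)
        noise = rng.normal(0, 1.0, size=(cells_per_patient, n_markers))
        for c in range(cells_per_patient):
            rows.append([f"{pid}_c{c}", pid, *(base + noise[c])])
    cell_expression = pd.DataFrame(rows, columns=["cell_id", "patient_id", *markers])

    tgt_groups = rng.integers(n_groups, size=n_target)
    tgt_ids = [f"T{i + 1:04d}" for i in range(n_target)]
    tgt_values = profiles[tgt_groups] + rng.normal(0, 0.5, size=(n_target, n_markers))
    target_expression = pd.DataFrame(tgt_values, index=tgt_ids, columns=markers)

    lp = hazard_per_group * tgt_groups.astype(float)
    death = rng.exponential(1.0 / (0.02 * np.exp(lp)))
    censor = rng.uniform(0, 120, size=n_target)
    outcome = SurvivalOutcome(
        tgt_ids, np.maximum(np.minimum(death, censor), 1e-6),
        (death <= censor).astype(int),
    )
    src_groups_s = pd.Series(src_groups, index=cell_expression["patient_id"].unique())
    tgt_groups_s = pd.Series(tgt_groups, index=tgt_ids)
    return cell_expression, src_groups_s, target_expression, tgt_groups_s, outcome
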