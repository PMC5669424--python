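"""Tab-separated table adapters and run configuration.

Predictor tables carry one row per stimulus and the 24 canonical
predictor columns (optionally split into horizontal ``H...`` and rotated
vertical ``V...`` orientation pairs, whose arithmetic mean is formed on
read), plus the four per-axis symmetry columns MSA..MSD.  Rating tables
are long format: one row per (participant, stimulus) with an integer 1-5
rating and an optional session label that drives the repeat-exclusion
flag (a stimulus re-rated in a later session does not enter the mean).
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import PREDICTOR_NAMES, FeatureConfig, PhaseCongruencyConfig
from .pattern_sim import AnnealingSchedule
from .symmetry import AXIS_COLUMNS


class SchemaError(ValueError):
    """A table does not match the expected layout."""


_ID_COLUMNS = ("stimulus", "id", "pattern", "image", "name")
_EXTRA_OK = ("complexity.mn", "complexity", "mean_rating")


def read_predictor_table(path, strict: bool = True) -> pd.DataFrame:
    """Read a tab-separated predictor table.

    The 24 canonical predictors must each be present either directly or
    as an ``H<name>``/``V<name>`` orientation pair (merged by arithmetic
    mean).  Per-axis columns MSA..MSD are kept when present.  Unknown
    columns raise a :class:`SchemaError` naming them unless
    ``strict=False``.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    id_col = next((c for c in cols if c.lower() in _ID_COLUMNS), None)
    if id_col is not None:
        df = df.set_index(id_col)
        cols.remove(id_col)
    out = {}
    used = set()
    missing = []
    for name in PREDICTOR_NAMES:
        if name in cols:
            out[name] = pd.to_numeric(df[name])
            used.add(name)
        elif f"H{name}" in cols and f"V{name}" in cols:
            out[name] = (pd.to_numeric(df[f"H{name}"]) + pd.to_numeric(df[f"V{name}"])) / 2.0
            used.update((f"H{name}", f"V{name}"))
        else:
            missing.append(name)
    if missing:
        raise SchemaError(f"predictor table lacks required column(s): {missing}")
    for name in AXIS_COLUMNS:
        if name in cols:
            out[name] = pd.to_numeric(df[name])
            used.add(name)
    unknown = [c for c in cols if c not in used and c.lower() not in _EXTRA_OK]
    if unknown and strict:
        raise SchemaError(f"unknown column(s) in predictor table: {unknown}")
    table = pd.DataFrame(out, index=df.index)
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise SchemaError("predictor table contains non-finite values")
    return table


def write_predictor_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.insert(0, "stimulus", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_rating_table(path) -> pd.DataFrame:
    """Read a long-format rating table (participant, stimulus, rating).

    Ratings must be integers 1-5; a violation is reported with its line
    number (header = line 1).  When a ``session`` column is present,
    repeat ratings of a stimulus in any session after the first session
    in which it appeared are flagged ``excluded`` so they do not enter
    mean complexity.
    """
    df = pd.read_csv(path, sep="\t")
    required = ("participant", "stimulus", "rating")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"rating table lacks required column(s): {missing}")
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad = df.index[~ratings.isin((1, 2, 3, 4, 5))]
    if len(bad):
        line = int(bad[0]) + 2  # header is line 1
        raise SchemaError(
            f"invalid rating {df['rating'].iloc[bad[0]]!r} on line {line}: "
            "ratings must be integers 1-5"
        )
    df["rating"] = ratings.astype(int)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    elif "session" in df.columns:
        first = df.groupby("stimulus")["session"].transform("min")
        df["excluded"] = df["session"] > first
    else:
        df["excluded"] = False
    return df


def write_rating_table(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ModelConfig:
    k_max: int = 3
    folds: int = 10
    n_estimators: int = 500


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 0
    px_per_cell: int = 74
    annealing: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ann = AnnealingSchedule(**raw.pop("annealing", {}))
        feat_raw = raw.pop("features", {})
        phc = PhaseCongruencyConfig(**feat_raw.pop("phc", {}))
        feat = FeatureConfig(phc=phc, **feat_raw)
        model = ModelConfig(**raw.pop("model", {}))
        return cls(annealing=ann, features=feat, model=model, **raw)


def environment_versions() -> dict:
    """Library versions recorded in run logs (encoder pinning)."""
    import PIL
    import skimage
    import sklearn
    import statsmodels

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "pillow": PIL.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
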