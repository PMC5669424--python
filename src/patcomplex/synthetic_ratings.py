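"""Simulated complexity ratings with a two-factor generative structure.

Perceived visual complexity is modelled as the sum of a quantitative
factor (amount of content; positive weight) and a structural factor
(symmetry; negative weight), with per-participant random intercepts and
random slopes on both factors, a per-stimulus random intercept, Gaussian
residual noise, and discretisation to the 1-5 rating scale by rounding
and clipping.  The latent truth (per-participant slopes, random
intercepts) is returned alongside the ratings so recovery tests can
check every modeling operation without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PREDICTOR_NAMES
from .symmetry import AXIS_COLUMNS


class SimulationError(ValueError):
    """Invalid rating-simulation input."""


@dataclass(frozen=True)
class RatingSimSpec:
    """Generative parameters for simulated ratings.

    Slopes act on z-standardised predictors; ``beta_sym`` is expected to
    be negative (symmetry reduces perceived complexity).  All SDs are on
    the latent rating scale.
    """

    beta0: float = 3.0
    beta_quant: float = 0.5
    beta_sym: float = -0.4
    slope_sd_quant: float = 0.0
    slope_sd_sym: float = 0.0
    intercept_sd_participant: float = 0.2
    intercept_sd_stimulus: float = 0.1
    noise_sd: float = 0.5
    n_participants: int = 50
    seed: int = 0
    quant_col: str = "RMSGIF"
    sym_col: str = "MS"

    def __post_init__(self) -> None:
        sds = (
            self.slope_sd_quant,
            self.slope_sd_sym,
            self.intercept_sd_participant,
            self.intercept_sd_stimulus,
            self.noise_sd,
        )
        if any(s < 0 for s in sds):
            raise SimulationError("all SDs must be non-negative")
        if self.n_participants < 1:
            raise SimulationError("need at least one participant")


@dataclass(frozen=True)
class LatentTruth:
    """Per-participant and per-stimulus latent effects actually drawn."""

    participant_intercepts: pd.Series
    participant_slopes_quant: pd.Series
    participant_slopes_sym: pd.Series
    stimulus_intercepts: pd.Series
    spec: RatingSimSpec


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise SimulationError(f"constant predictor column {col.name!r}")
    return (col - col.mean()) / sd


def simulate_ratings(
    table: pd.DataFrame, spec: RatingSimSpec
) -> tuple[pd.DataFrame, LatentTruth]:
    """Draw a long-format rating table from the two-factor model.

    ``table`` must contain the quantitative and structural predictor
    columns named in the spec; they are z-standardised internally.  Every
    participant rates every stimulus.  Ratings are the latent scores
    rounded to the nearest integer and clipped to 1-5.
    """
    for col in (spec.quant_col, spec.sym_col):
        if col not in table.columns:
            raise SimulationError(f"predictor column {col!r} missing from table")
    rng = np.random.default_rng(spec.seed)
    quant = _standardize(table[spec.quant_col]).to_numpy()
    sym = _standardize(table[spec.sym_col]).to_numpy()
    stimuli = table.index.to_numpy()
    n_stim = len(stimuli)
    participants = np.arange(1, spec.n_participants + 1)

    u_p = rng.normal(0.0, spec.intercept_sd_participant, spec.n_participants)
    b_q = rng.normal(0.0, spec.slope_sd_quant, spec.n_participants)
    b_s = rng.normal(0.0, spec.slope_sd_sym, spec.n_participants)
    v_s = rng.normal(0.0, spec.intercept_sd_stimulus, n_stim)

    latent = (
        spec.beta0
        + u_p[:, None]
        + v_s[None, :]
        + (spec.beta_quant + b_q)[:, None] * quant[None, :]
        + (spec.beta_sym + b_s)[:, None] * sym[None, :]
        + rng.normal(0.0, spec.noise_sd, (spec.n_participants, n_stim))
    )
    ratings = np.clip(np.rint(latent), 1, 5).astype(int)

    out = pd.DataFrame(
        {
            "participant": np.repeat(participants, n_stim),
            "stimulus": np.tile(stimuli, spec.n_participants),
            "rating": ratings.ravel(),
        }
    )
    truth = LatentTruth(
        participant_intercepts=pd.Series(u_p, index=participants),
        participant_slopes_quant=pd.Series(spec.beta_quant + b_q, index=participants),
        participant_slopes_sym=pd.Series(spec.beta_sym + b_s, index=participants),
        stimulus_intercepts=pd.Series(v_s, index=stimuli),
        spec=spec,
    )
    return out, truth


def synthetic_predictor_table(
    n_stimuli: int = 500,
    seed: int = 0,
    quant_fidelity: float = 0.15,
    sym_fidelity: float = 0.15,
    companion_noise: tuple[float, float] = (0.5, 1.0),
) -> pd.DataFrame:
    """Statistically simulated 24-column predictor table.

    Emulates the correlation structure of the real predictor battery with
    two latent factors: a quantitative factor measured most cleanly by
    RMSGIF and a structural (symmetry) factor measured most cleanly by
    MS, with every other column loading on one of the factors plus
    column-specific noise.  Columns are on an arbitrary (z-like) scale;
    per-axis columns MSA..MSD are included as noisy versions of the
    structural factor.  This synthetic table exists so that model-selection
    and recovery experiments do not require rendering and measuring
    thousands of images.
    """
    rng = np.random.default_rng(seed)
    quant = rng.normal(size=n_stimuli)
    struct = rng.normal(size=n_stimuli)
    cols: dict[str, np.ndarray] = {}
    quant_family = [
        "GIF", "PNG", "TIF", "JPG",
        "PHCMN", "PHCSD", "PHCMNSD", "CANMN", "CANSD", "CANMNSD",
        "PERMN", "PERSD", "PERMNSD", "RMSMN", "RMSSD", "RMSMNSD",
        "PHCGIF", "CANGIF", "PERGIF", "HG", "DCM",
    ]
    lo, hi = companion_noise
    for name in quant_family:
        cols[name] = quant + rng.uniform(lo, hi) * rng.normal(size=n_stimuli)
    cols["RMSGIF"] = quant + quant_fidelity * rng.normal(size=n_stimuli)
    cols["MS"] = struct + sym_fidelity * rng.normal(size=n_stimuli)
    cols["APB"] = rng.normal(size=n_stimuli)
    for name in AXIS_COLUMNS:
        cols[name] = struct + 0.3 * rng.normal(size=n_stimuli)
    index = pd.Index([f"s{i:04d}" for i in range(1, n_stimuli + 1)], name="stimulus")
    table = pd.DataFrame(cols, index=index)
    return table[[*PREDICTOR_NAMES, *AXIS_COLUMNS]]
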