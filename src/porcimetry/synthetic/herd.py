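"""Synthetic herd records emulating the farm dataset's marginal statistics.

Each record mimics one measured Duroc-line pig: breed (S21/S23), gender,
birth and determination dates, tape measurements in centimetres (chest,
abdominal, waist circumference; body length; height, a configurable
fraction missing) and the scale weight in kilograms.  Body measures share a
latent "frame size" factor so they correlate the way girth measurements do
on real animals; weight is a linear-plus-smooth function of the measures
with additive Gaussian noise, so the irreducible prediction error is known
exactly and learning-stage recovery can be tested against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError

__all__ = ["HERD_MOMENTS", "DEFAULT_WEIGHT_EFFECTS", "generate_herd_records"]

# latent-factor loadings: column = mean + load * u + sd_eps * eps
_STRUCTURE = {
    # column: (mean, factor loading, independent sd)
    "chest": (107.0, 4.0, 2.5),
    "abdominal": (112.0, 4.5, 2.5),
    "waist": (105.0, 4.2, 2.6),
    "length": (121.0, 3.5, 3.0),
    "height": (63.0, 1.8, 1.5),
    "age": (191.0, 6.0, 10.0),
}

#: implied marginal moments (mean, sd) of each generated column
HERD_MOMENTS = {
    col: (mu, float(np.hypot(load, sd)))
    for col, (mu, load, sd) in _STRUCTURE.items()
}

#: weight model: intercept plus per-column linear coefficients (kg per unit)
DEFAULT_WEIGHT_EFFECTS = {"intercept": -38.5, "abdominal": 0.9, "age": 0.25}

_FEMALE_FRACTION = 5438 / 9980
_S21_FRACTION = 8068 / 9980


def generate_herd_records(
    n: int,
    seed: int = 0,
    effect_spec: dict[str, float] | None = None,
    noise_sd_kg: float = 2.0,
    smooth_amplitude: float = 4.0,
    missing_height_fraction: float = 0.05,
) -> pd.DataFrame:
    """Generate ``n`` raw herd records.

    ``effect_spec`` maps column names (plus ``"intercept"``) to linear
    weight coefficients; ``smooth_amplitude`` scales a smooth saturating
    term ``A·tanh((abdominal − 112)/15)`` so the weight model is not purely
    linear.  Weight is computed from the *rounded* tape measures, so with
    zero noise it is an exact function of the printed columns.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if noise_sd_kg < 0 or not 0 <= missing_height_fraction <= 1:
        raise InvalidParameterError("invalid noise_sd_kg or missing_height_fraction")
    effects = DEFAULT_WEIGHT_EFFECTS if effect_spec is None else effect_spec
    rng = np.random.default_rng(seed)

    u = rng.normal(0.0, 1.0, n)
    cols: dict[str, np.ndarray] = {}
    for col, (mu, load, sd) in _STRUCTURE.items():
        cols[col] = mu + load * u + rng.normal(0.0, sd, n)
    cols["age"] = np.maximum(np.round(cols["age"]), 1.0)
    for col in ("chest", "abdominal", "waist", "length", "height"):
        cols[col] = np.round(np.maximum(cols[col], 1.0), 1)

    female = rng.random(n) < _FEMALE_FRACTION
    s21 = rng.random(n) < _S21_FRACTION

    det = pd.Timestamp("2019-01-01") + pd.to_timedelta(
        rng.integers(0, 730, n), unit="D"
    )
    birth = det - pd.to_timedelta(cols["age"].astype(int), unit="D")

    weight = np.full(n, float(effects.get("intercept", 0.0)))
    for col, coef in effects.items():
        if col == "intercept":
            continue
        if col not in cols:
            raise InvalidParameterError(f"unknown effect column {col!r}")
        weight = weight + coef * cols[col]
    if smooth_amplitude:
        weight = weight + smooth_amplitude * np.tanh((cols["abdominal"] - 112.0) / 15.0)
    if noise_sd_kg > 0:
        weight = weight + rng.normal(0.0, noise_sd_kg, n)

    height = cols["height"].astype(float)
    if missing_height_fraction > 0:
        height[rng.random(n) < missing_height_fraction] = np.nan

    return pd.DataFrame(
        {
            "breed": np.where(s21, "S21", "S23"),
            "gender": np.where(female, "female", "male"),
            "determination_date": det.strftime("%Y-%m-%d"),
            "birth_date": birth.strftime("%Y-%m-%d"),
            "chest": cols["chest"],
            "abdominal": cols["abdominal"],
            "waist": cols["waist"],
            "length": cols["length"],
            "height": height,
            "weight": weight,
        }
    )
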