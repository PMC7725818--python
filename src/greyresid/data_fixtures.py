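"""Embedded study data, seeded synthetic generators, and series I/O.

The embedded fixture is the cumulative count of confirmed COVID-19 cases in
South Africa (WHO situation reports): 40 training values for June 9 –
July 18 2020 and 10 test values for July 19 – 28.  The published source
table carries two transcription defects, shipped here as an explicit
correction table rather than silently patched:

* position 18 (June 26) prints 1,118,375 where the cumulative record reads
  118,375 (the printed value breaks monotonicity by an order of magnitude);
* the final training row (July 9–18) verbatim duplicates the test row
  (July 19–28), which is impossible for a cumulative series.  The corrected
  values are the WHO situation-report counts for those dates (situation
  reports republish the previous day's national announcement, which is why
  the test row's July 19 value 350,879 is the South African July 18 count).
  Fitting GM(1,1) to the corrected series reproduces the grey action
  quantity published with this dataset (b = 51434) to seven significant
  figures, confirming the reconstruction.

``raw`` mode returns every printed digit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CovidFixture",
    "SyntheticSpec",
    "covid_fixture",
    "gen_exponential",
    "gen_wavy_residual",
    "read_series",
    "write_series",
]

# Training table as printed (dates June 9 .. July 18 2020), row-major.
_TRAIN_PRINTED = [
    50879, 52991, 55421, 58568, 61927, 65736, 70038, 73533, 76334, 80412,
    83890, 87715, 92681, 97302, 101590, 106108, 111796, 1118375, 124590, 131800,
    138134, 144264, 151209, 159333, 168061, 177124, 187977, 196750, 205721, 215855,
    350879, 364328, 373628, 381798, 394948, 408052, 421996, 434200, 445433, 452530,
]

# Test table as printed (dates July 19 .. July 28 2020).
_TEST_PRINTED = [
    350879, 364328, 373628, 381798, 394948, 408052, 421996, 434200, 445433, 452530,
]

# (1-based index, printed value, corrected value, rationale)
_CORRECTIONS: List[Tuple[int, float, float, str]] = [
    (
        18,
        1_118_375,
        118_375,
        "printed 1,118,375 breaks monotonic growth between 111,796 and 124,590; "
        "the WHO cumulative record for June 26 reads 118,375",
    ),
] + [
    (
        31 + i,
        float(_TRAIN_PRINTED[30 + i]),
        float(v),
        "final training row duplicates the test row verbatim; replaced with the "
        "WHO situation-report count for July %d 2020" % (9 + i),
    )
    for i, v in enumerate(
        [224665, 238339, 250687, 264184, 276242, 287796, 298292, 311049, 324221, 337594]
    )
]


@dataclass(frozen=True)
class CovidFixture:
    """South African cumulative COVID-19 case counts, train (40) and test (10)."""

    train: np.ndarray
    test: np.ndarray
    corrections: List[Tuple[int, float, float, str]]
    mode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", np.asarray(self.train, dtype=float))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=float))


def covid_fixture(mode: str = "corrected") -> CovidFixture:
    """The embedded case-count fixture.

    ``corrected`` (default) applies the documented correction table;
    ``raw`` reproduces the printed tables digit for digit.
    """
    if mode not in ("raw", "corrected"):
        raise ValueError(f"unknown fixture mode {mode!r}")
    train = np.asarray(_TRAIN_PRINTED, dtype=float)
    if mode == "corrected":
        train = train.copy()
        for idx, printed, fixed, _why in _CORRECTIONS:
            assert train[idx - 1] == printed
            train[idx - 1] = fixed
    return CovidFixture(
        train=train,
        test=np.asarray(_TEST_PRINTED, dtype=float),
        corrections=list(_CORRECTIONS),
        mode=mode,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the seeded synthetic series generators.

    Defaults emulate the study's setting: a cumulative-count-like level
    (around 5e4) growing a few percent per step over 40 steps, with small
    additive noise.  The ``wavy_residual`` kind superimposes a relative
    sinusoid so that grey-model residuals alternate in sign — the case the
    classical residual-tail correction cannot handle.
    """

    kind: str = "wavy_residual"
    c: float = 50_000.0
    ratio: float = 1.05
    n: int = 40
    noise_sd: float = 250.0
    wave_amp: float = 0.05
    wave_period: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.ratio <= 0:
            raise ValueError("c and ratio must be > 0")
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if self.kind not in ("exponential", "wavy_residual"):
            raise ValueError(f"unknown kind {self.kind!r}")


_RESAMPLE_CAP = 100


def _add_noise(trend: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    out = trend + rng.normal(0.0, spec.noise_sd, size=trend.size) if spec.noise_sd > 0 else trend.copy()
    for _ in range(_RESAMPLE_CAP):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = trend[bad] + rng.normal(0.0, spec.noise_sd, size=int(bad.sum()))
    raise ValueError("could not generate a strictly positive series; lower noise_sd")


def gen_exponential(spec: SyntheticSpec) -> np.ndarray:
    """Near-exponential growth: ``x(k) = c * ratio^(k-1) + noise``, strictly positive."""
    k = np.arange(spec.n)
    return _add_noise(spec.c * spec.ratio**k, spec)


def gen_wavy_residual(spec: SyntheticSpec) -> np.ndarray:
    """Exponential trend with a relative sinusoid, defeating tail modellability.

    ``x(k) = c * ratio^(k-1) * (1 + wave_amp * sin(2 pi k / wave_period)) + noise``
    (1-based k).  With the default amplitude and period the grey-model
    residuals alternate in sign, so no one-signed tail of length >= 5 exists.
    """
    k = np.arange(1, spec.n + 1)
    trend = spec.c * spec.ratio ** (k - 1) * (
        1.0 + spec.wave_amp * np.sin(2.0 * np.pi * k / spec.wave_period)
    )
    return _add_noise(trend, spec)


def generate(spec: SyntheticSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "exponential":
        return gen_exponential(spec)
    return gen_wavy_residual(spec)


def read_series(path) -> pd.DataFrame:
    """Read a series CSV: a `value` column (header optional when single-column)
    and an optional `date` column carried through untouched."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=False)
    if raw.empty:
        raise ValueError(f"empty file: {path}")
    header = [str(v).strip().lower() for v in raw.iloc[0]]
    if "value" in header:
        df = raw.iloc[1:].reset_index(drop=True)
        df.columns = header
    else:
        if raw.shape[1] != 1:
            raise ValueError(
                f"{path}: multi-column file needs a header with a 'value' column"
            )
        df = raw.rename(columns={0: "value"})
    values = []
    # python float() is correctly rounded, so written digits round-trip exactly
    for i, cell in enumerate(df["value"]):
        try:
            values.append(float(cell))
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric or blank value at data row {i + 1}"
            ) from None
        if np.isnan(values[-1]):
            raise ValueError(f"{path}: non-numeric or blank value at data row {i + 1}")
    out = pd.DataFrame({"value": np.array(values, dtype=float)})
    if "date" in df.columns:
        out.insert(0, "date", df["date"].to_numpy())
    return out


def write_series(series, path, dates=None) -> None:
    """Write values (and optional dates) as a CSV with full float precision."""
    values = np.asarray(series, dtype=float)
    df = pd.DataFrame({"value": values})
    if dates is not None:
        df.insert(0, "date", list(dates))
    df.to_csv(path, index=False, float_format="%.17g")
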