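"""Mean GM(1,1) grey model: construction, simulation and residual-tail correction.

The grey model GM(1,1) fits an exponential trend to a short, positive,
equally spaced series by (i) accumulating it (1-AGO), (ii) regressing each
raw value on the mean of consecutive accumulated values (the *background
value*), and (iii) restoring forecasts by differencing the solution of the
whitening equation ``dx1/dt + a*x1 = b``.  The development coefficient ``a``
sets the exponential rate (negative ``a`` means growth) and the grey action
quantity ``b`` is the constant forcing term.

All series are 1-based in the documented contract (index ``k = 1..n``);
internal storage is ordinary 0-based numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GMModel",
    "ResidualSeries",
    "ResidualGMCorrection",
    "ago",
    "iago",
    "background",
    "fit_gm",
    "simulate",
    "residuals",
    "find_modellable_tail",
    "residual_gm_correct",
]

#: Degeneracy guard for the b/a division in the time-response equation.
DEFAULT_A_TOL = 1e-10

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GMModel:
    """Fitted mean GM(1,1) model.

    Attributes
    ----------
    a : float
        Development coefficient (per time step).  Negative for growing series.
    b : float
        Grey action quantity, in the units of the observations.
    x0_1 : float
        First observation, used as the initial condition of the time response.
    n_fit : int
        Number of observations the model was fitted on.
    degenerate : bool
        True when ``|a| <= a_tol``; :func:`simulate` refuses such models.
    """

    a: float
    b: float
    x0_1: float
    n_fit: int
    a_tol: float = DEFAULT_A_TOL
    degenerate: bool = field(default=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "a": self.a,
                "b": self.b,
                "x0_1": self.x0_1,
                "n_fit": self.n_fit,
                "schema_version": SCHEMA_VERSION,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "GMModel":
        obj = json.loads(payload)
        return cls(a=obj["a"], b=obj["b"], x0_1=obj["x0_1"], n_fit=obj["n_fit"])


@dataclass(frozen=True)
class ResidualSeries:
    """Signed residuals ``eps(k) = x(k) - xhat(k)`` with tail metadata.

    ``k0`` is the 1-based start of the longest suffix whose residuals all
    share one strict sign and satisfy ``n - k0 >= 4`` (the classical
    modellability condition), or ``None`` when no such suffix exists.
    """

    eps: np.ndarray
    k0: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps", np.asarray(self.eps, dtype=float))

    def __len__(self) -> int:
        return len(self.eps)

    @property
    def tail_modellable(self) -> bool:
        return self.k0 is not None


@dataclass(frozen=True)
class ResidualGMCorrection:
    """Classical residual-tail correction: a second GM(1,1) on ``|eps|``.

    ``tail`` is fitted on the absolute residuals over ``k0..n``; ``sign`` is
    the common sign of those residuals and is reapplied to the tail model's
    output when correcting forecasts.
    """

    base: GMModel
    tail: GMModel
    k0: int
    sign: int

    def corrected(self, n: int) -> np.ndarray:
        """Corrected restored series over ``k = 1..n``.

        Values before ``k0`` are the plain GM(1,1) restored values; from
        ``k0`` on, the tail model's restored absolute residual (derivative
        form, factor ``-a_theta``) is added with the tail's sign.
        """
        base_vals = simulate(self.base, n)
        out = base_vals.copy()
        at, bt = self.tail.a, self.tail.b
        k = np.arange(1, n + 1)
        mask = k >= self.k0
        corr = -at * (self.tail.x0_1 - bt / at) * np.exp(-at * (k[mask] - self.k0))
        out[mask] = base_vals[mask] + self.sign * corr
        return out


def _as_array(series: Sequence[float], name: str = "series") -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError("empty series")
    return arr


def ago(series: Sequence[float]) -> np.ndarray:
    """First-order accumulated generating operation (cumulative sum)."""
    return np.cumsum(_as_array(series))


def iago(accumulated: Sequence[float]) -> np.ndarray:
    """Inverse AGO: first differencing, keeping the first value.

    Exact inverse of :func:`ago`: ``iago(ago(s)) == s``.
    """
    arr = _as_array(accumulated, "accumulated series")
    return np.diff(arr, prepend=0.0)


def background(accumulated: Sequence[float]) -> np.ndarray:
    """Background values: means of consecutive AGO values, ``k = 2..n``."""
    arr = _as_array(accumulated, "accumulated series")
    if arr.size < 2:
        raise ValueError("background values need at least 2 accumulated values")
    return 0.5 * (arr[1:] + arr[:-1])


def fit_gm(series: Sequence[float], a_tol: float = DEFAULT_A_TOL) -> GMModel:
    """Fit the mean GM(1,1) by least squares.

    Solves ``x0(k) = -a*z(k) + b`` over ``k = 2..n`` where ``z`` are the
    background values of the accumulated series.

    Raises
    ------
    ValueError
        If fewer than 4 observations, any observation is not strictly
        positive, or the normal equations are singular.
    """
    x0 = _as_array(series)
    if x0.size < 4:
        raise ValueError("too few observations: GM(1,1) needs n >= 4")
    if np.any(x0 <= 0):
        bad = int(np.argmax(x0 <= 0)) + 1
        raise ValueError(
            f"non-positive value at k={bad}: GM(1,1) requires strictly positive series"
        )
    z = background(ago(x0))
    design = np.column_stack([-z, np.ones_like(z)])
    rhs = x0[1:]
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 2:
        raise ValueError("singular normal equations in GM(1,1) fit")
    a, b = float(sol[0]), float(sol[1])
    return GMModel(
        a=a,
        b=b,
        x0_1=float(x0[0]),
        n_fit=int(x0.size),
        a_tol=a_tol,
        degenerate=abs(a) <= a_tol,
    )


def simulate(model: GMModel, n: int) -> np.ndarray:
    """Restored (simulated/forecast) series over ``k = 1..n``.

    ``out(1) = x0_1`` by convention, so the first residual is always zero;
    for ``k >= 2`` the restored value is
    ``(1 - e^a) (x0_1 - b/a) e^{-a (k-1)}``.  ``n`` beyond ``n_fit`` yields
    out-of-sample forecasts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(model.a) <= model.a_tol:
        raise ValueError("degenerate development coefficient: |a| <= a_tol")
    k = np.arange(2, n + 1)
    out = np.empty(n, dtype=float)
    out[0] = model.x0_1
    out[1:] = (1.0 - np.exp(model.a)) * (model.x0_1 - model.b / model.a) * np.exp(
        -model.a * (k - 1)
    )
    return out


def residuals(actual: Sequence[float], simulated: Sequence[float]) -> ResidualSeries:
    """Residual series ``eps(k) = actual(k) - simulated(k)`` with tail metadata."""
    a = _as_array(actual, "actual")
    s = _as_array(simulated, "simulated")
    if a.size != s.size:
        raise ValueError(f"length mismatch: actual has {a.size}, simulated has {s.size}")
    eps = a - s
    res = ResidualSeries(eps=eps)
    return ResidualSeries(eps=eps, k0=find_modellable_tail(res))


def find_modellable_tail(res: ResidualSeries) -> Optional[int]:
    """Smallest 1-based ``k0`` with a strictly one-signed suffix of length >= 5.

    The classical condition: all ``eps(k)`` for ``k >= k0`` share one strict
    sign (zeros break a sign run) and ``n - k0 >= 4``.  Returns ``None`` when
    no suffix qualifies.
    """
    eps = res.eps
    n = eps.size
    for k0 in range(1, n + 1):
        if n - k0 < 4:
            break
        tail = eps[k0 - 1 :]
        if np.all(tail > 0) or np.all(tail < 0):
            return k0
    return None


def residual_gm_correct(
    base: GMModel, res: ResidualSeries, k0: Optional[int] = None
) -> ResidualGMCorrection:
    """Fit the classical residual-tail correction at ``k0``.

    A second GM(1,1) is fitted on the absolute residuals ``|eps(k0)| ..
    |eps(n)|``; the tail's common sign is stored and reapplied when the
    correction is evaluated.
    """
    if k0 is None:
        k0 = res.k0
    if k0 is None:
        raise ValueError("residual tail is not modellable: no valid k0")
    n = len(res)
    if not (1 <= k0 <= n) or n - k0 < 4:
        raise ValueError(f"invalid tail start k0={k0} for residual length {n}")
    tail_eps = res.eps[k0 - 1 :]
    if np.any(tail_eps == 0):
        raise ValueError("ambiguous sign: residual tail contains zeros")
    signs = np.sign(tail_eps)
    if not np.all(signs == signs[0]):
        raise ValueError(f"residual tail at k0={k0} does not share one strict sign")
    tail_model = fit_gm(np.abs(tail_eps))
    return ResidualGMCorrection(
        base=base, tail=tail_model, k0=k0, sign=int(signs[0])
    )
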