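"""Movement-mode annotation by expectation-maximization binary clustering.

Each interior fix of a trip gets a speed (step displacement over step
duration) and an unsigned turning angle.  A four-component Gaussian mixture
constrained to the quadrants of a binary split per variable is fitted by EM:
the components share a low and a high level per variable, so each component
mean is (speed level, turn level) and the four components are exactly the
quadrant codes LL, LH, HL, HH (speed letter first, H = high).  Commuting —
straight fast travel between nest and foraging patch — is the HL mode.

Delimiters (the binary split values) are placed midway between the fitted
low and high level means, so labels are tied to the geometry of the split
rather than to component indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MODES = ("LL", "LH", "HL", "HH")  # speed letter first, then turn


def derive_kinematics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-fix speed (m/s) and unsigned turning angle (rad) from a trip.

    Speed at fix i is the displacement from fix i to i+1 over the elapsed
    time (the last fix copies the previous speed).  The turn at an interior
    fix is the absolute angle between the incoming and outgoing headings;
    endpoint fixes copy the nearest interior turn.
    """
    if len(fixes) < 3:
        raise ValueError("need at least three fixes for kinematics")
    t = fixes["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or unsorted timestamps")
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    dx, dy, dt = np.diff(x), np.diff(y), np.diff(t)
    step_speed = np.hypot(dx, dy) / dt
    speed = np.empty(len(t))
    speed[:-1] = step_speed
    speed[-1] = step_speed[-1]

    heading = np.arctan2(dy, dx)
    dh = np.abs(np.diff(heading))
    dh = np.minimum(dh, 2 * np.pi - dh)  # wrap to [0, pi]
    turn = np.empty(len(t))
    turn[1:-1] = dh
    turn[0] = dh[0]
    turn[-1] = dh[-1]
    return pd.DataFrame({"speed": speed, "turn": turn}, index=fixes.index)


@dataclass
class EmbcResults:
    """Fitted binary-clustering state: delimiters, labels, diagnostics."""

    modes: np.ndarray                      # per-point quadrant code
    delimiters: tuple[float, float]        # (speed split m/s, turn split rad)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False
    params: dict = field(default_factory=dict)

    @property
    def commuting(self) -> np.ndarray:
        return self.modes == "HL"

    def smooth(self, window: int = 3) -> "EmbcResults":
        return EmbcResults(
            modes=smooth_modes(self.modes, window),
            delimiters=self.delimiters,
            loglik_trace=self.loglik_trace,
            converged=self.converged,
            degenerate=self.degenerate,
            params=self.params,
        )


class EmbcModel:
    """Quadrant-constrained 2-component-per-variable Gaussian mixture.

    Parameters are a low and a high mean/variance per variable plus four
    component weights; EM alternates responsibilities with weighted-average
    updates, and the log-likelihood is non-decreasing up to `tol`.
    Initialisation splits each variable at its median.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 200, min_sigma: float = 1e-3):
        self.tol = tol
        self.max_iter = max_iter
        self.min_sigma = min_sigma

    # component k -> (speed level, turn level); 0 = low, 1 = high
    _LEVELS = {"LL": (0, 0), "LH": (0, 1), "HL": (1, 0), "HH": (1, 1)}

    def fit(self, points: pd.DataFrame | np.ndarray, seed: int = 0) -> EmbcResults:
        pts = np.asarray(points[["speed", "turn"]] if isinstance(points, pd.DataFrame) else points, float)
        finite = np.isfinite(pts).all(axis=1)
        if finite.sum() < 8:
            raise ValueError("need at least 8 finite (speed, turn) points")
        s, u = pts[:, 0], pts[:, 1]
        if np.ptp(s[finite]) == 0 and np.ptp(u[finite]) == 0:
            return EmbcResults(
                modes=np.full(len(pts), "LL", dtype=object),
                delimiters=(float(s[finite][0]), float(u[finite][0])),
                degenerate=True,
            )

        rng = np.random.default_rng(seed)
        mu = np.empty((2, 2))   # [variable, level]
        sg = np.empty((2, 2))
        for v, col in enumerate((s, u)):
            c = col[finite]
            split = np.median(c)
            lo, hi = c[c <= split], c[c > split]
            if len(hi) == 0:  # constant-ish variable: nudge apart
                lo = hi = c
            mu[v] = [lo.mean(), hi.mean()]
            if mu[v, 0] == mu[v, 1]:
                mu[v, 1] = mu[v, 0] + max(1e-6, 1e-3 * abs(mu[v, 0]) + 1e-6)
            sg[v] = [max(lo.std(), self.min_sigma), max(hi.std(), self.min_sigma)]
        w = np.full(4, 0.25) + rng.uniform(-1e-3, 1e-3, 4)
        w /= w.sum()

        codes = list(MODES)
        lls: list[float] = []
        converged = False
        sf, uf = s[finite], u[finite]
        for _ in range(self.max_iter):
            # E-step
            logp = np.empty((finite.sum(), 4))
            for k, code in enumerate(codes):
                ls, lu = self._LEVELS[code]
                logp[:, k] = (
                    np.log(w[k])
                    + norm.logpdf(sf, mu[0, ls], sg[0, ls])
                    + norm.logpdf(uf, mu[1, lu], sg[1, lu])
                )
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            ll = float(lse.sum())
            r = np.exp(logp - lse[:, None])
            if lls and ll - lls[-1] < self.tol:
                lls.append(ll)
                converged = True
                break
            lls.append(ll)
            # M-step
            w = r.mean(axis=0)
            w = np.clip(w, 1e-12, None)
            w /= w.sum()
            for v, col in enumerate((sf, uf)):
                for lev in (0, 1):
                    rk = sum(
                        r[:, k] for k, code in enumerate(codes)
                        if self._LEVELS[code][v] == lev
                    )
                    tot = rk.sum()
                    if tot > 0:
                        mu[v, lev] = (rk * col).sum() / tot
                        var = (rk * (col - mu[v, lev]) ** 2).sum() / tot
                        sg[v, lev] = max(np.sqrt(var), self.min_sigma)
                # keep the level semantics: low mean <= high mean
                if mu[v, 0] > mu[v, 1]:
                    mu[v] = mu[v][::-1]
                    sg[v] = sg[v][::-1]

        delim = (float(mu[0].mean()), float(mu[1].mean()))
        labels_f = np.array(codes, dtype=object)[np.argmax(r, axis=1)]
        modes = np.full(len(pts), "LL", dtype=object)
        modes[finite] = labels_f
        return EmbcResults(
            modes=modes,
            delimiters=delim,
            loglik_trace=lls,
            converged=converged,
            params={"mu": mu.copy(), "sigma": sg.copy(), "weights": w.copy()},
        )


def embc_fit(
    points: pd.DataFrame | np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> EmbcResults:
    """Functional wrapper around :class:`EmbcModel`."""
    return EmbcModel(tol=tol, max_iter=max_iter).fit(points, seed=seed)


def smooth_modes(modes: np.ndarray, window: int = 3) -> np.ndarray:
    """Replace each label by the modal label in its centered window.

    Ties keep the original label; `window` must be odd.  Accounts for
    temporal association of behavioral modes along the track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    modes = np.asarray(modes, dtype=object)
    if window == 1:
        return modes.copy()
    half = window // 2
    out = modes.copy()
    n = len(modes)
    for i in range(n):
        win = modes[max(0, i - half): min(n, i + half + 1)]
        vals, counts = np.unique(win.astype(str), return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        if len(winners) == 1 and winners[0] != modes[i]:
            out[i] = winners[0]
    return out


def annotate_commuting(
    fixes: pd.DataFrame,
    seed: int = 0,
    smooth_window: int = 3,
    group_cols: tuple[str, ...] = ("bird_id",),
) -> pd.DataFrame:
    """Fit the clustering per group (per bird-year) and flag commuting fixes.

    Returns a copy of `fixes` with speed, turn, mode and commuting columns.
    Groups too small to fit get mode LL (not commuting).
    """
    out = fixes.copy()
    out["mode"] = "LL"
    out["speed"] = np.nan
    out["turn"] = np.nan
    cols = [c for c in group_cols if c in out.columns]
    groups = out.groupby(list(cols)) if cols else [(None, out)]
    for _, grp in groups:
        if len(grp) < 8:
            continue
        kin = derive_kinematics(grp)
        res = EmbcModel().fit(kin, seed=seed).smooth(smooth_window)
        out.loc[grp.index, "speed"] = kin["speed"]
        out.loc[grp.index, "turn"] = kin["turn"]
        out.loc[grp.index, "mode"] = res.modes
    out["commuting"] = out["mode"] == "HL"
    return out
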