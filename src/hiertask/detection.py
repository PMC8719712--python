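"""Extrema-detection choice model for internal-node queries, and variants.

After querying a node, a single evidence pulse ``e`` is compared against two
symmetric criteria at ±Φ. If ``e`` exceeds +Φ the right child is chosen, if
it falls below −Φ the left child is chosen, and otherwise the sample is
discarded and the node is queried again (a re-query). The criterion is the
product of a per-level base criterion φ_ℓ and a term that decays with the
number of immediately preceding queries at the node (the streak counter
n_q):

    Φ(ℓ, n_q) = φ_ℓ · (1 + exp(−λ·n_q))

The model has six free parameters (κ, γ, φ₁, φ₂, φ₃, λ) fitted by maximum
likelihood to the trinomial choice (right / left / re-query) made after each
query. An integration variant accumulates evidence across successive
queries of the same node, comparing the running sum against the same
criterion schedule; it serves as the optimality-inspired alternative in
model comparisons. Additional parameter-tying variants (shared criterion
with per-level signal-to-noise, per-level both, constant variance, and a
query-order-dependent criterion) are exposed for BIC comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import optimize
from scipy.special import erfc

from .task import EvidenceParams, PULSE_DURATION_S

_SQRT2 = np.sqrt(2.0)

OUTCOMES = ("right", "left", "requery")


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the detection model.

    kappa : signal-to-noise (evidence mean per unit coherence·second)
    gamma : slope of the variance on coherence
    phi   : base criteria per tree level, highest level first
    lam   : decay rate of the criterion with the streak counter
    """

    kappa: float = 16.0
    gamma: float = 1.5
    phi: tuple = (0.45, 0.35, 0.25)
    lam: float = 1.0
    t: float = PULSE_DURATION_S

    def __post_init__(self):
        if self.kappa <= 0 or self.gamma < 0 or self.lam < 0:
            raise ValueError("require kappa>0, gamma>=0, lam>=0")
        if any(p < 0 for p in self.phi):
            raise ValueError("base criteria must be nonnegative")

    @property
    def evidence(self) -> EvidenceParams:
        return EvidenceParams(self.kappa, self.gamma, self.t)

    def to_dict(self):
        return {"kappa": self.kappa, "gamma": self.gamma,
                "phi": list(self.phi), "lam": self.lam, "t": self.t}

    @classmethod
    def from_dict(cls, d):
        return cls(d["kappa"], d["gamma"], tuple(d["phi"]), d["lam"],
                   d.get("t", PULSE_DURATION_S))


def criterion(level, n_q, params: DetectionParams):
    """Collapsing criterion Φ = φ_ℓ·(1 + exp(−λ·n_q))."""
    level = np.asarray(level)
    n_q = np.asarray(n_q)
    phi = np.asarray(params.phi)[level - 1]
    return phi * (1.0 + np.exp(-params.lam * n_q))


def choice_probs(c, d, level, n_q, params: DetectionParams):
    """Trinomial (right, left, re-query) probabilities of one pulse.

    Gaussian tail masses beyond the two criteria:
    p_right = ½·erfc((Φ−μ)/(√2σ)), p_left = ½·erfc((Φ+μ)/(√2σ)).
    """
    mu = params.evidence.mean(c, d)
    sd = params.evidence.sd(c)
    phi = criterion(level, n_q, params)
    p_right = 0.5 * erfc((phi - mu) / (_SQRT2 * sd))
    p_left = 0.5 * erfc((phi + mu) / (_SQRT2 * sd))
    p_requery = 1.0 - p_right - p_left
    return p_right, p_left, np.maximum(p_requery, 0.0)


# ---------------------------------------------------------------------------
# Detection likelihood
# ---------------------------------------------------------------------------

def _encode_outcomes(outcome):
    codes = pd.Categorical(outcome, categories=OUTCOMES).codes
    if (codes < 0).any():
        raise ValueError(f"outcomes must be one of {OUTCOMES}")
    return codes.astype(np.intp)


def detection_loglik(table: pd.DataFrame, params: DetectionParams) -> float:
    """Summed log likelihood of trinomial choices in a query table.

    The table needs columns (c, d, level, n_q, outcome); by convention only
    queries followed by a re-query or by a query at one of the two child
    nodes enter this likelihood.
    """
    if len(table) == 0:
        return 0.0
    codes = _encode_outcomes(table["outcome"].to_numpy())
    pr, pl, pq = choice_probs(table["c"].to_numpy(float),
                              table["d"].to_numpy(float),
                              table["level"].to_numpy(int),
                              table["n_q"].to_numpy(int), params)
    p = np.choose(codes, [pr, pl, pq])
    return float(np.sum(np.log(np.maximum(p, 1e-300))))


# ---------------------------------------------------------------------------
# Integration variant
# ---------------------------------------------------------------------------

def _integration_tables(c: float, levels, params: DetectionParams,
                        n_pulses: int, grid_points: int):
    """First-exit probabilities of the accumulated evidence for one
    coherence (rightward motion) at several tree levels at once.

    The surviving (truncated) density of the running sum is propagated on
    a uniform evidence grid by FFT convolution with the pulse kernel.
    Returns {level: (uncond, cond)} where each array has shape
    (n_pulses, 3) = (exit right, exit left, stay) — unconditional, and
    conditional on having survived the previous pulses.
    """
    if grid_points < 201:
        raise ValueError("grid too coarse")
    evid = params.evidence
    mu = float(evid.mean(c, 1))
    sd = float(evid.sd(c))
    levels = sorted(set(int(l) for l in levels))
    phis = np.array([params.phi[l - 1] for l in levels])
    span = 2.0 * phis.max() + abs(mu) + 8.0 * sd
    G = int(grid_points)
    x = np.linspace(-span, span, G)
    dx = x[1] - x[0]
    m = int(np.ceil((abs(mu) + 8.0 * sd) / dx))
    u = np.arange(-m, m + 1) * dx
    kernel = np.exp(-0.5 * ((u - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)) * dx
    nfft = sp_fft.next_fast_len(G + len(kernel) - 1)
    Kf = sp_fft.rfft(kernel, nfft)
    L = len(levels)
    dens = np.tile(np.exp(-0.5 * ((x - mu) / sd) ** 2)
                   / (sd * np.sqrt(2 * np.pi)) * dx, (L, 1))
    uncond = np.empty((L, n_pulses, 3))
    surv = np.ones(L)
    first = True
    for k in range(n_pulses):
        phi_k = phis * (1.0 + np.exp(-params.lam * k))
        if not first:
            conv = sp_fft.irfft(sp_fft.rfft(dens, nfft, axis=1) * Kf,
                                nfft, axis=1)
            dens = conv[:, m:m + G]
        for li in range(L):
            # exit masses via the interpolated cumulative sum so that the
            # likelihood is smooth in phi (no grid-cell staircase)
            cs = np.cumsum(dens[li])
            total = cs[-1]
            F_lo, F_hi = np.interp([-phi_k[li], phi_k[li]], x, cs)
            if first:
                pr = 0.5 * erfc((phi_k[li] - mu) / (_SQRT2 * sd))
                pl = 0.5 * erfc((phi_k[li] + mu) / (_SQRT2 * sd))
                stay = max(1.0 - pr - pl, 0.0)
            else:
                pr = total - F_hi
                pl = F_lo
                stay = F_hi - F_lo
            uncond[li, k] = (pr, pl, stay)
            lo = np.searchsorted(x, -phi_k[li], side="left")
            hi = np.searchsorted(x, phi_k[li], side="right")
            dens[li, :lo] = 0.0
            dens[li, hi:] = 0.0
            rem = dens[li].sum()
            if rem > 0:
                dens[li] *= stay / rem
        first = False
    cond = uncond.copy()
    for li in range(L):
        surv = 1.0
        for k in range(n_pulses):
            cond[li, k] /= max(surv, 1e-300)
            surv = uncond[li, k, 2]
    return {l: (uncond[i], cond[i]) for i, l in enumerate(levels)}


def integration_probs(c, d, level, params: DetectionParams, n_pulses: int,
                      grid_points: int = 2001, _conditional: bool = False):
    """Exit probabilities of the accumulated evidence under the integration
    model.

    The running sum S_k of k pulses is compared against ±Φ(ℓ, k−1); the
    decision terminates at the first exit. Returns an (n_pulses, 3) array of
    *unconditional* probabilities that the sum first exits right / left /
    stays inside at pulse k (the last column is the survival probability
    through pulse k). With ``_conditional=True`` the first two columns are
    instead conditioned on having survived the previous pulses.
    """
    uncond, cond = _integration_tables(c, [level], params, n_pulses,
                                       grid_points)[int(level)]
    out = cond if _conditional else uncond
    if d == -1:  # mirror symmetry: swap right/left
        out = out[:, [1, 0, 2]]
    return out


def integration_loglik(table: pd.DataFrame, params: DetectionParams,
                       grid_points: int = 2001) -> float:
    """Log likelihood of a query table under the integration model.

    Each row is one pulse of a streak (pulse index = n_q); its probability
    is the conditional probability of its outcome given that the running
    sum stayed inside the criteria on all previous pulses of the streak.
    Leftward-motion rows are folded onto rightward by mirror symmetry.
    """
    if len(table) == 0:
        return 0.0
    codes = _encode_outcomes(table["outcome"].to_numpy())
    c = table["c"].to_numpy(float)
    d = table["d"].to_numpy(int)
    level = table["level"].to_numpy(int)
    n_q = table["n_q"].to_numpy(int)
    # mirror: flip d to +1 and swap right/left outcomes
    flip = d == -1
    codes = np.where(flip & (codes < 2), 1 - codes, codes)
    loglik = 0.0
    df = pd.DataFrame({"c": c, "level": level, "n_q": n_q, "code": codes})
    for ci, cgrp in df.groupby("c", sort=False):
        kmax = int(cgrp["n_q"].max()) + 1
        tabs = _integration_tables(ci, cgrp["level"].unique(), params, kmax,
                                   grid_points)
        for li, grp in cgrp.groupby("level", sort=False):
            cond = tabs[int(li)][1]
            p = cond[grp["n_q"].to_numpy(int), grp["code"].to_numpy(int)]
            loglik += float(np.sum(np.log(np.maximum(p, 1e-300))))
    return loglik


# ---------------------------------------------------------------------------
# Variants and fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of a choice-model variant."""

    variant: str
    params: dict
    loglik: float
    n_obs: int
    n_params: int
    seed: int
    n_starts: int
    converged: bool
    start_logliks: list = field(default_factory=list)

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def detection_params(self) -> DetectionParams:
        """Best-fit parameters mapped onto a DetectionParams (where the
        variant defines per-level κ this uses the mean κ)."""
        p = self.params
        kappa = p.get("kappa", np.mean([p[k] for k in p if k.startswith("kappa")]))
        phi = tuple(p.get(f"phi{i}", p.get("phi", 0.0)) for i in (1, 2, 3))
        return DetectionParams(kappa, p.get("gamma", 0.0), phi, p.get("lam", 0.0))

    def to_json(self, path=None):
        d = {"variant": self.variant, "params": self.params,
             "loglik": self.loglik, "bic": self.bic, "aic": self.aic,
             "n_obs": self.n_obs, "n_params": self.n_params,
             "seed": self.seed, "n_starts": self.n_starts,
             "converged": self.converged}
        if path is None:
            return json.dumps(d, indent=1)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# each variant: (param names, bounds, function vec -> loglik closure builder)
_B = {"kappa": (0.5, 80.0), "gamma": (0.0, 10.0), "phi": (1e-4, 4.0),
      "lam": (0.0, 8.0), "eta": (-4.0, 0.0)}

VARIANTS = {
    "detection": ["kappa", "gamma", "phi1", "phi2", "phi3", "lam"],
    "integration": ["kappa", "gamma", "phi1", "phi2", "phi3", "lam"],
    "1phi3kappa": ["kappa1", "kappa2", "kappa3", "gamma", "phi", "lam"],
    "3phi3kappa": ["kappa1", "kappa2", "kappa3", "gamma",
                   "phi1", "phi2", "phi3", "lam"],
    "gamma0": ["kappa", "phi1", "phi2", "phi3", "lam"],
    "query_order": ["kappa", "gamma", "phi0", "phiinf", "eta"],
}


def _bounds_for(name: str):
    for key, b in _B.items():
        if name.startswith(key) and not name.startswith("phiinf"):
            return b
    if name in ("phi0", "phiinf"):
        return _B["phi"]
    raise KeyError(name)


def _rowwise_probs(vec, names, arrays):
    """Right/left/re-query probabilities per row for any detection-style
    variant (everything except `integration`)."""
    p = dict(zip(names, vec))
    c, d, level, n_q, q = arrays["c"], arrays["d"], arrays["level"], \
        arrays["n_q"], arrays.get("q")
    if "kappa" in p:
        kappa = p["kappa"]
    else:
        kappa = np.array([p["kappa1"], p["kappa2"], p["kappa3"]])[level - 1]
    gamma = p.get("gamma", 0.0)
    t = PULSE_DURATION_S
    mu = kappa * d * c * t
    sd = np.sqrt(t * (1.0 + c * gamma))
    if "phi0" in p:  # query-order criterion
        phi = p["phiinf"] + (p["phi0"] - p["phiinf"]) * np.exp(p["eta"] * (q - 1))
    elif "phi" in p:
        phi = p["phi"] * (1.0 + np.exp(-p["lam"] * n_q))
    else:
        base = np.array([p["phi1"], p["phi2"], p["phi3"]])[level - 1]
        phi = base * (1.0 + np.exp(-p["lam"] * n_q))
    pr = 0.5 * erfc((phi - mu) / (_SQRT2 * sd))
    pl = 0.5 * erfc((phi + mu) / (_SQRT2 * sd))
    return pr, pl, np.maximum(1.0 - pr - pl, 0.0)


def fit_detection(table: pd.DataFrame, variant: str = "detection",
                  seed: int = 0, n_starts: int = 8,
                  grid_points: int = 2001, maxiter: int = 2000) -> FitResult:
    """Fit a choice-model variant by multi-start maximum likelihood.

    Starts are drawn from a seeded Latin-hypercube over the parameter
    bounds and refined with Nelder–Mead; the fit is deterministic given the
    seed and invariant to row order.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {list(VARIANTS)}")
    names = VARIANTS[variant]
    bounds = [_bounds_for(n) for n in names]
    arrays = {
        "c": table["c"].to_numpy(float),
        "d": table["d"].to_numpy(float),
        "level": table["level"].to_numpy(int),
        "n_q": table["n_q"].to_numpy(int),
    }
    codes = _encode_outcomes(table["outcome"].to_numpy())
    if variant == "query_order":
        if "q" not in table.columns:
            raise ValueError("query_order variant needs a 'q' column "
                             "(order of the query in the trial)")
        arrays["q"] = table["q"].to_numpy(float)

    if variant == "integration":
        sub = table[["c", "d", "level", "n_q", "outcome"]]

        def nll(vec):
            p = dict(zip(names, vec))
            params = DetectionParams(p["kappa"], p["gamma"],
                                     (p["phi1"], p["phi2"], p["phi3"]), p["lam"])
            return -integration_loglik(sub, params, grid_points=grid_points)
    else:
        def nll(vec):
            pr, pl, pq = _rowwise_probs(vec, names, arrays)
            p = np.choose(codes, [pr, pl, pq])
            return -float(np.sum(np.log(np.maximum(p, 1e-300))))

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # stratified (Latin hypercube) starts
    u = (rng.permuted(np.tile(np.arange(n_starts), (len(names), 1)), axis=1).T
         + rng.random((n_starts, len(names)))) / n_starts
    starts = list(lo + u * (hi - lo))
    if variant == "integration":
        # the detection-model optimum is an excellent informed start for
        # the (identically parameterized) integration likelihood
        det_fit = fit_detection(table, "detection", seed=seed,
                                n_starts=n_starts, maxiter=maxiter)
        informed = np.clip([det_fit.params[n] for n in names], lo, hi)
        starts = [informed] + starts[:max(n_starts - 1, 1)]

    best = None
    start_lls = []
    any_converged = False
    # the integration likelihood costs ~10 ms/eval; a looser simplex
    # tolerance (log-likelihood to ~1e-3) is ample for BIC comparisons
    nm_opts = ({"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3}
               if variant == "integration" else
               {"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-7})
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead", bounds=bounds,
                                options=nm_opts)
        start_lls.append(-float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = dict(zip(names, map(float, best.x)))
    return FitResult(variant=variant, params=params, loglik=-float(best.fun),
                     n_obs=len(table), n_params=len(names), seed=seed,
                     n_starts=n_starts, converged=any_converged,
                     start_logliks=start_lls)


def simulate_streak(c, d, level, params: DetectionParams,
                    rng: np.random.Generator, integrate: bool = False,
                    max_pulses: int = 500):
    """Simulate one query streak at a node until a child choice.

    Returns (rows, choice, last_e) where rows is a list of
    (n_q, outcome, e) tuples, one per pulse, choice is +1 (right) or −1
    (left), and last_e is the evidence sample that triggered the choice.
    """
    total = 0.0
    rows = []
    evid = params.evidence
    mu = float(evid.mean(c, d))
    sd = float(evid.sd(c))
    phi_base = params.phi[level - 1]
    for k in range(max_pulses):
        e = float(rng.normal(mu, sd))
        stat = total + e if integrate else e
        phi_k = phi_base * (1.0 + np.exp(-params.lam * k))
        if stat > phi_k:
            rows.append((k, "right", e))
            return rows, +1, e
        if stat < -phi_k:
            rows.append((k, "left", e))
            return rows, -1, e
        rows.append((k, "requery", e))
        total = stat
    # pathological long streak: force the sign of the statistic
    choice = +1 if (total if integrate else e) >= 0 else -1
    rows[-1] = (max_pulses - 1, "right" if choice > 0 else "left", e)
    return rows, choice, e
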