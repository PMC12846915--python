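"""Fixed-mean von Mises models for rule responses.

Interference at retest is quantified by fitting a two-component von Mises
mixture to a subject's rule responses, with the component means fixed at
the two task rules (theta_A, theta_B) and two free parameters: the mixing
weight pi on the rule-B component and a single shared concentration kappa.
pi is the probability of responding with the newly learned rule B when
retested on task A — the interference weight.

Strategy classification compares single fixed-mean von Mises fits at
theta_A vs theta_B by log likelihood: subjects (or networks) whose retest
responses are better explained by rule B are *lumpers* (they merged the
tasks), those returning to rule A are *splitters*.

Estimation is by expectation maximisation with multiple restarts over a
grid of initial (pi, kappa); kappa is updated by solving the Bessel-ratio
equation A(kappa) = I1(kappa)/I0(kappa) = R with Newton iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "vonmises_logpdf",
    "VonMisesMixture",
    "VonMisesMixtureResults",
    "FixedMeanVonMises",
    "SingleFit",
    "fit_mixture_em",
    "fit_single",
    "classify_taskB_learner",
    "classify_lumper_splitter",
    "interference",
]

KAPPA_FLOOR = 1e-3
KAPPA_CAP = 1e3
EM_TOL = 1e-6
EM_MAX_ITER = 500
#: restart grid for EM initialisation
PI_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
KAPPA_GRID = (1.0, 5.0, 20.0, 80.0)


def vonmises_logpdf(x_deg, mu_deg, kappa):
    """Log density of a von Mises distribution, angles in degrees.

    log f(x) = kappa * cos(x - mu) - log(2 pi I0(kappa)), evaluated with the
    exponentially scaled Bessel function for numerical stability at large
    kappa.  kappa = 0 is the uniform distribution on the circle.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    d = np.deg2rad(np.asarray(x_deg, dtype=float) - mu_deg)
    log_i0 = np.log(special.i0e(kappa)) + kappa
    out = kappa * np.cos(d) - np.log(2.0 * np.pi) - log_i0
    return out if out.ndim else float(out)


def _bessel_ratio(kappa):
    return special.i1e(kappa) / special.i0e(kappa)


def _solve_kappa(r: float) -> float:
    """Solve A(kappa) = r for the ML concentration given mean resultant r.

    Uses the standard piecewise approximation as the starting point and
    polishes with Newton iterations; clamped to [KAPPA_FLOOR, KAPPA_CAP].
    """
    if not np.isfinite(r) or r <= 0.0:
        return KAPPA_FLOOR
    if r >= 1.0:
        return KAPPA_CAP
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    k = float(np.clip(k, KAPPA_FLOOR, KAPPA_CAP))
    for _ in range(50):
        a = _bessel_ratio(k)
        # dA/dkappa = 1 - A/kappa - A^2
        da = 1.0 - a / k - a * a
        if da <= 0:
            break
        step = (a - r) / da
        k_new = float(np.clip(k - step, KAPPA_FLOOR, KAPPA_CAP))
        if abs(k_new - k) < 1e-12:
            k = k_new
            break
        k = k_new
    return k


@dataclass
class SingleFit:
    """Maximum-likelihood fixed-mean von Mises fit."""

    mean_deg: float
    kappa: float
    loglik: float
    n: int
    at_floor: bool  # kappa clamped (non-positive resultant toward the mean)


class FixedMeanVonMises:
    """Single von Mises with a known mean; only kappa is estimated."""

    def __init__(self, responses_deg, mean_deg: float):
        self.responses = np.asarray(responses_deg, dtype=float).ravel()
        if self.responses.size < 2:
            raise ValueError("need at least two responses")
        self.mean_deg = float(mean_deg)

    def fit(self) -> SingleFit:
        r = float(np.mean(np.cos(np.deg2rad(self.responses - self.mean_deg))))
        kappa = _solve_kappa(r)
        llf = float(np.sum(vonmises_logpdf(self.responses, self.mean_deg, kappa)))
        return SingleFit(
            mean_deg=self.mean_deg,
            kappa=kappa,
            loglik=llf,
            n=self.responses.size,
            at_floor=r <= 0.0,
        )


def fit_single(responses_deg, theta_deg: float) -> SingleFit:
    """Functional wrapper around :class:`FixedMeanVonMises`."""
    return FixedMeanVonMises(responses_deg, theta_deg).fit()


@dataclass
class VonMisesMixtureResults:
    """Fitted two-component fixed-mean mixture.

    ``pi`` is the weight on the rule-B component; ``loglik_path`` is the
    per-iteration log likelihood of the winning restart (non-decreasing by
    construction of EM).
    """

    pi: float
    kappa: float
    loglik: float
    n: int
    converged: bool
    n_iter: int
    theta_a: float
    theta_b: float
    loglik_path: np.ndarray

    def summary(self) -> str:
        lines = [
            "Von Mises mixture (fixed means, shared kappa)",
            "=" * 46,
            f"theta_A: {self.theta_a:8.2f} deg   theta_B: {self.theta_b:8.2f} deg",
            f"n obs:   {self.n}",
            f"pi (rule B weight): {self.pi:8.4f}",
            f"kappa:              {self.kappa:8.3f}",
            f"log likelihood:     {self.loglik:10.3f}",
            f"converged: {self.converged} after {self.n_iter} iterations",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fitted mixture density over the circle of rule responses."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(-180.0, 180.0, 721)
        # density per radian -> per degree
        dens = np.exp(_mixture_logpdf(grid, self.theta_a, self.theta_b, self.pi, self.kappa)) * np.pi / 180.0
        ax.plot(grid, dens, lw=2)
        ax.set_xlabel("rule response (deg)")
        ax.set_ylabel("density (per deg)")
        return ax


def _mixture_logpdf(x_deg, theta_a, theta_b, pi, kappa):
    la = vonmises_logpdf(x_deg, theta_a, kappa)
    lb = vonmises_logpdf(x_deg, theta_b, kappa)
    stacked = np.stack([la + np.log1p(-pi) if pi < 1 else np.full_like(la, -np.inf),
                        lb + (np.log(pi) if pi > 0 else -np.inf)])
    return special.logsumexp(stacked, axis=0)


class VonMisesMixture:
    """Two-component von Mises mixture with predetermined means.

    Parameters
    ----------
    responses_deg : array-like
        Rule responses (signed circular offsets, degrees).
    theta_a, theta_b : float
        The two fixed component means: the task A and task B rules.
    """

    def __init__(self, responses_deg, theta_a: float, theta_b: float):
        self.responses = np.asarray(responses_deg, dtype=float).ravel()
        if self.responses.size < 2:
            raise ValueError("need at least two responses")
        d = np.mod(theta_a - theta_b, 360.0)
        if d == 0.0:
            raise ValueError("theta_a and theta_b must differ")
        self.theta_a = float(theta_a)
        self.theta_b = float(theta_b)
        # component kernels depend only on fixed means: precompute cosines
        self._cos_a = np.cos(np.deg2rad(self.responses - self.theta_a))
        self._cos_b = np.cos(np.deg2rad(self.responses - self.theta_b))

    # -- EM ----------------------------------------------------------------
    def _loglik(self, pi, kappa):
        log_i0 = np.log(special.i0e(kappa)) + kappa
        la = kappa * self._cos_a - np.log(2 * np.pi) - log_i0
        lb = kappa * self._cos_b - np.log(2 * np.pi) - log_i0
        with np.errstate(divide="ignore"):
            m = np.logaddexp(np.log1p(-pi) + la if pi < 1 else np.full_like(la, -np.inf),
                             np.log(pi) + lb if pi > 0 else np.full_like(lb, -np.inf))
        return float(np.sum(m)), la, lb

    def _em(self, pi0, kappa0, tol, max_iter):
        pi, kappa = float(pi0), float(kappa0)
        path = []
        prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            llf, la, lb = self._loglik(pi, kappa)
            if llf < prev - 1e-8:
                raise AssertionError("EM log likelihood decreased")
            path.append(llf)
            if llf - prev < tol and it > 1:
                converged = True
                break
            prev = llf
            # E-step: responsibility of the rule-B component
            with np.errstate(divide="ignore"):
                log_wa = (np.log1p(-pi) if pi < 1 else -np.inf) + la
                log_wb = (np.log(pi) if pi > 0 else -np.inf) + lb
            resp = np.exp(log_wb - np.logaddexp(log_wa, log_wb))
            # M-step
            pi = float(np.clip(np.mean(resp), 0.0, 1.0))
            r = float(np.mean(resp * self._cos_b + (1.0 - resp) * self._cos_a))
            kappa = _solve_kappa(r)
        return pi, kappa, path[-1], converged, len(path), np.asarray(path)

    def fit(
        self,
        pi_grid=PI_GRID,
        kappa_grid=KAPPA_GRID,
        tol: float = EM_TOL,
        max_iter: int = EM_MAX_ITER,
    ) -> VonMisesMixtureResults:
        """Run EM from every point of the restart grid; keep the best."""
        best = None
        for pi0 in pi_grid:
            for k0 in kappa_grid:
                pi, kappa, llf, conv, nit, path = self._em(pi0, k0, tol, max_iter)
                if best is None or llf > best[2]:
                    best = (pi, kappa, llf, conv, nit, path)
        pi, kappa, llf, conv, nit, path = best
        return VonMisesMixtureResults(
            pi=pi,
            kappa=kappa,
            loglik=llf,
            n=self.responses.size,
            converged=conv,
            n_iter=nit,
            theta_a=self.theta_a,
            theta_b=self.theta_b,
            loglik_path=path,
        )


def fit_mixture_em(responses_deg, theta_a, theta_b, **fit_kwargs) -> VonMisesMixtureResults:
    """Functional wrapper around :class:`VonMisesMixture`."""
    return VonMisesMixture(responses_deg, theta_a, theta_b).fit(**fit_kwargs)


def classify_taskB_learner(taskB_rule_responses, theta_a, theta_b) -> bool:
    """Did this subject switch to rule B during task B training?

    Compares fixed-mean fits at the two rules on task B rule responses
    (first task B block excluded upstream — no opportunity to have learned
    yet).  Subjects still using rule A are excluded from interference
    analyses: interference is only interpretable if task B was learned.
    """
    fa = fit_single(taskB_rule_responses, theta_a)
    fb = fit_single(taskB_rule_responses, theta_b)
    return bool(fb.loglik > fa.loglik)


def classify_lumper_splitter(retest_rule_responses, theta_a, theta_b) -> str:
    """Label a task-B learner by their retest behaviour.

    ``"splitter"`` if the rule A fit wins (returned to the original rule),
    ``"lumper"`` if the rule B fit wins (interference carried the new rule
    back into task A).  Ties break toward splitter.
    """
    fa = fit_single(retest_rule_responses, theta_a)
    fb = fit_single(retest_rule_responses, theta_b)
    return "lumper" if fb.loglik > fa.loglik else "splitter"


def interference(retest_rule_responses, theta_a, theta_b, condition: str = "near") -> float:
    """Mixture weight pi on rule B at retest: probability of using rule B.

    Undefined in the Same condition where the rules coincide.
    """
    if condition == "same":
        raise ValueError("interference is undefined in the Same condition (rules coincide)")
    return fit_mixture_em(retest_rule_responses, theta_a, theta_b).pi
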