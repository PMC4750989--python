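"""GLV system identification from longitudinal taxa count tables.

The continuous dynamics dx/dt = diag(x)(r + A x), assumed piecewise
constant over one-day sampling intervals, discretize to the linear
regression

    log x_i(t_{k+1}) - log x_i(t_k) = r_i + sum_j a_ij x_j(t_k) + e_i(k),

so each taxon's growth rate and interaction row can be estimated jointly by
Tikhonov-regularized least squares with the closed form
Theta_hat = Y Phi^T (Phi Phi^T + lambda I)^{-1}.  Preprocessing follows the
conventions used on real stool time series: zero read counts are replaced
by one, relative abundances are computed before the logarithm, and only
pairs of samples taken on consecutive days enter the regression.  Strongly
interacting taxa are ranked by the standard deviation of their column of
the estimated interaction matrix.

Because sequencing observes composition rather than biomass, regressing on
relative abundances rescales the interaction estimates by the (unobserved)
total abundance; rankings and structure are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import GLVSystem, integrate_to_steady
from .metacommunity import LocalCommunity

__all__ = [
    "TaxaTimeSeries",
    "RegressionProblem",
    "SysIdResult",
    "build_regression",
    "ridge_fit",
    "cross_validate_lambda",
    "sis_scores",
    "permute_days",
    "synth_timeseries",
    "default_lambda_grid",
]


def default_lambda_grid(num: int = 50) -> np.ndarray:
    """Log-spaced regularization grid in [1e-4, 10]."""
    return np.logspace(-4, 1, num)


@dataclass
class TaxaTimeSeries:
    """A taxa-by-sample count table with integer day timestamps."""

    taxa: list
    counts: np.ndarray
    timestamps: np.ndarray
    subject: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.timestamps = np.asarray(self.timestamps, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.taxa), len(self.timestamps)):
            raise ValueError("counts must be taxa x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=pd.Index(self.taxa, name="taxon"),
                          columns=self.timestamps)
        df.to_csv(Path(path), sep="\t")

    @classmethod
    def from_tsv(cls, path, subject: str = "") -> "TaxaTimeSeries":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(taxa=list(df.index), counts=df.to_numpy(),
                   timestamps=np.array([int(c) for c in df.columns]),
                   subject=subject or Path(path).stem)


@dataclass
class RegressionProblem:
    """Aligned log-difference targets Y (n x M) and regressors Phi ((n+1) x M)."""

    Y: np.ndarray
    Phi: np.ndarray
    pair_index: list  # (sample index k, sample index of the next day)
    taxa: list = field(default_factory=list)


@dataclass
class SysIdResult:
    Theta_hat: np.ndarray  # n x (n+1); column 0 = growth rates, rest = A_hat
    lam: float
    taxa: list = field(default_factory=list)
    cv_errors: dict = field(default_factory=dict)

    @property
    def r_hat(self) -> np.ndarray:
        return self.Theta_hat[:, 0]

    @property
    def A_hat(self) -> np.ndarray:
        return self.Theta_hat[:, 1:]

    def save(self, outdir) -> None:
        """Write the parameter matrix, SIS ranking and fit metadata."""
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        taxa = self.taxa if self.taxa else list(range(len(self.Theta_hat)))
        pd.DataFrame(self.Theta_hat, index=pd.Index(taxa, name="taxon"),
                     columns=["growth_rate"] + [str(t) for t in taxa]
                     ).to_csv(outdir / "theta.tsv", sep="\t")
        sis_scores(self).to_csv(outdir / "sis_ranking.tsv", sep="\t")
        meta = {"lam": self.lam}
        if self.cv_errors:
            meta["cv_errors"] = {str(k): v for k, v in self.cv_errors.items()}
        (outdir / "fit.json").write_text(json.dumps(meta, indent=1))


def _abundances(ts: TaxaTimeSeries, relative: bool,
                count_scale: float | None) -> np.ndarray:
    x = np.asarray(ts.counts, dtype=float)
    x[x == 0] = 1.0  # pseudo-count so logarithms are finite
    if relative:
        x = x / x.sum(axis=0, keepdims=True)
    elif count_scale is not None:
        x = x / count_scale
    return x


def build_regression(ts: TaxaTimeSeries, relative: bool = True,
                     count_scale: float | None = None) -> RegressionProblem:
    """Assemble the one-day log-difference regression from a count table.

    Zero counts become one read; abundances are normalized per sample when
    ``relative`` (the default, matching the real-data protocol); only pairs
    of samples exactly one day apart are used.  With ``relative=False`` the
    raw counts serve as abundances, optionally divided by ``count_scale``
    (e.g. the sequencing depth) to put the regressors on the dynamical
    scale -- the log-differences are scale invariant, so this only rescales
    the estimated interaction matrix.
    """
    x = _abundances(ts, relative, count_scale)
    pairs = [(k, k + 1) for k in range(len(ts.timestamps) - 1)
             if ts.timestamps[k + 1] - ts.timestamps[k] == 1]
    if not pairs:
        raise ValueError("no consecutive-day sample pairs; cannot regress")
    k0 = np.array([a for a, _ in pairs])
    k1 = np.array([b for _, b in pairs])
    Y = np.log(x[:, k1]) - np.log(x[:, k0])
    Phi = np.vstack([np.ones(len(pairs)), x[:, k0]])
    return RegressionProblem(Y=Y, Phi=Phi, pair_index=pairs, taxa=list(ts.taxa))


def ridge_fit(problem: RegressionProblem, lam: float) -> SysIdResult:
    """Tikhonov solution Y Phi^T (Phi Phi^T + lam I)^{-1}.

    Evaluated through the equivalent stacked least-squares problem
    min || [Phi^T; sqrt(lam) I] Theta^T - [Y^T; 0] ||_F (QR/SVD based, never
    an explicit inverse), which is numerically far better conditioned than
    forming the Gram matrix.  lam = 0 requires Phi to have full row rank.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    Phi, Y = problem.Phi, problem.Y
    d = Phi.shape[0]
    if lam == 0:
        if np.linalg.matrix_rank(Phi) < d:
            raise np.linalg.LinAlgError(
                "regressor matrix is rank deficient; use lam > 0")
        design, target = Phi.T, Y.T
    else:
        design = np.vstack([Phi.T, np.sqrt(lam) * np.eye(d)])
        target = np.vstack([Y.T, np.zeros((d, Y.shape[0]))])
    Theta = np.linalg.lstsq(design, target, rcond=None)[0].T
    return SysIdResult(Theta_hat=Theta, lam=lam, taxa=problem.taxa)


def _chronological_split(problem: RegressionProblem, train_frac: float = 2 / 3):
    M = problem.Y.shape[1]
    cut = int(np.floor(train_frac * M))
    if cut < 1 or cut >= M:
        raise ValueError("too few pairs for a train/test split")
    tr = RegressionProblem(Y=problem.Y[:, :cut], Phi=problem.Phi[:, :cut],
                           pair_index=problem.pair_index[:cut], taxa=problem.taxa)
    te = RegressionProblem(Y=problem.Y[:, cut:], Phi=problem.Phi[:, cut:],
                           pair_index=problem.pair_index[cut:], taxa=problem.taxa)
    return tr, te


def cross_validate_lambda(ts_list: list[TaxaTimeSeries], grid=None,
                          relative: bool = True, train_frac: float = 2 / 3,
                          ) -> tuple[float, dict]:
    """Pick the regularization weight by chronological hold-out.

    Per subject, the chronologically first two-thirds of usable pairs train
    and the final third tests; for each lambda the subjects are fitted
    separately and the squared prediction errors of the test blocks are
    summed.  Ties go to the smaller lambda.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    splits = [_chronological_split(build_regression(ts, relative=relative), train_frac)
              for ts in ts_list]
    errors = {}
    for lam in np.sort(grid):
        total = 0.0
        for tr, te in splits:
            fit = ridge_fit(tr, lam)
            resid = te.Y - fit.Theta_hat @ te.Phi
            total += float((resid ** 2).sum())
        errors[float(lam)] = total
    lam_opt = min(errors, key=lambda l: (errors[l], l))
    return lam_opt, errors


def sis_scores(result: SysIdResult) -> pd.Series:
    """Per-taxon interaction-strength score, descending.

    The score is the standard deviation of the taxon's column of the
    estimated interaction matrix (the spread of its outgoing effects); the
    growth-rate column is excluded.  Ties keep taxon order.
    """
    scores = result.A_hat.std(axis=0, ddof=0)
    taxa = result.taxa if result.taxa else list(range(len(scores)))
    ser = pd.Series(scores, index=taxa, name="sis_score")
    return ser.sort_values(ascending=False, kind="stable")


def permute_days(ts: TaxaTimeSeries, seed: int = 0) -> TaxaTimeSeries:
    """Shuffle the assignment of sample columns to collection dates.

    Timestamps stay fixed; the multiset of count columns is preserved.  The
    consecutive-day rule downstream then pairs compositions that are not in
    fact one day apart, destroying the temporal signal -- the negative
    control for the identification pipeline.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ts.timestamps))
    return TaxaTimeSeries(taxa=list(ts.taxa), counts=ts.counts[:, perm],
                          timestamps=ts.timestamps.copy(),
                          subject=f"{ts.subject}:permuted")


def synth_timeseries(lc: LocalCommunity, days: int, noise_c: float = 0.0,
                     dropout_prob: float = 0.0, depth: int = 100_000,
                     seed: int = 0, scheme: str = "euler", dt: float = 1.0,
                     count_mode: str = "multinomial",
                     restart_every: int | None = None,
                     ) -> TaxaTimeSeries:
    """Simulate a daily-sampled count table from a local community.

    ``scheme="euler"`` iterates the exact discrete multiplicative map
    x(t+1) = x(t) * exp(dt * (r + A x(t))), the generative model the
    regression assumes, so identification is exact up to count noise;
    ``scheme="ode"`` samples the continuous GLV trajectory daily and hence
    carries genuine discretization error.  ``noise_c`` adds Gaussian noise
    c*sqrt(dt) to each log-increment (multiplicative abundance noise).
    Sampled days are dropped independently with ``dropout_prob``.  Counts
    are drawn multinomially with ``depth`` reads per sample
    (``count_mode="multinomial"``), or deterministically rounded
    (``count_mode="rounded"``, for noise-free recovery studies; the column
    sums then vary by the rounding).

    ``restart_every`` re-randomizes the state every so many samples,
    emulating repeated large perturbations (diet shifts, travel): without
    them a noise-free trajectory parks at the fixed point and the regression
    loses identifiability.  Each restart also skips one calendar day so the
    across-restart pair, which the dynamics do not generate, is excluded by
    the consecutive-day rule.
    """
    rng = np.random.default_rng(seed)
    system = GLVSystem.from_local(lc)
    x = rng.uniform(0.1, 1.0, lc.p)
    traj = np.empty((days, lc.p))
    stamps_all = np.empty(days, dtype=int)
    day = 1
    for d in range(days):
        if restart_every and d > 0 and d % restart_every == 0:
            x = rng.uniform(0.1, 1.0, lc.p)
            day += 1  # gap day: the restart jump never forms a usable pair
        traj[d] = x
        stamps_all[d] = day
        day += 1
        incr = dt * (system.r + system.A @ x)
        if noise_c > 0:
            incr = incr + noise_c * np.sqrt(dt) * rng.standard_normal(lc.p)
        if scheme == "euler":
            x = x * np.exp(incr)
        elif scheme == "ode":
            res = integrate_to_steady(system, x, horizon=dt, grid_dt=dt / 10)
            x = res.x_star
            if noise_c > 0:
                x = x * np.exp(noise_c * np.sqrt(dt) * rng.standard_normal(lc.p))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("synthetic trajectory diverged")
    keep = rng.random(days) >= dropout_prob
    traj, stamps = traj[keep], stamps_all[keep]
    if len(stamps) == 0:
        raise ValueError("all days dropped; no samples left")
    rel = traj / traj.sum(axis=1, keepdims=True)
    if count_mode == "multinomial":
        counts = np.vstack([rng.multinomial(depth, row) for row in rel]).T
    elif count_mode == "rounded":
        counts = np.floor(traj.T * depth + 0.5).astype(np.int64)
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    taxa = [f"sp{j}" for j in lc.members]
    return TaxaTimeSeries(taxa=taxa, counts=counts, timestamps=stamps,
                          subject=f"synthetic-lc{lc.nu}")
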