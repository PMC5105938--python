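"""Learned components: the apnea/non-apnea partition and the DPMG model.

The partition is a soft-margin RBF support-vector machine separating
apneic from non-apneic states.  The DPMG (Dirichlet-process mixture of
Gaussians) clusters the embedded states by collapsed Gibbs sampling
under a conjugate Normal–Inverse-Wishart base measure; each sizeable
cluster then receives a *local* Gaussian process regressing the next
state on the current one, so a query state yields a full Gaussian
predictive distribution for its one-minute-ahead successor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gammaln
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InsufficientDataError, OsaprogError
from .io_formats import APNEA

logger = logging.getLogger(__name__)

MIN_CLUSTER_FOR_GP = 5


# ---------------------------------------------------------------------------
# SVM-RBF apnea/non-apnea partition
# ---------------------------------------------------------------------------

@dataclass
class ApneaPartition:
    """Trained RBF-SVM separating apneic (positive) from non-apneic states."""

    svc: SVC
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cv_sensitivity: float
    cv_specificity: float
    n_support: int

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed score; positive ⇒ apneic side of the separating plane."""
        return self.svc.decision_function(self._transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean apnea prediction per row."""
        return self.decision_function(X) > 0


def train_partition(X: np.ndarray, labels, gamma: float | str = "scale",
                    C: float = 1.0, k_folds: int = 5,
                    seed: int = 0) -> ApneaPartition:
    """Train the RBF-SVM partition with k-fold CV sensitivity/specificity.

    ``labels`` may be booleans (True = apnea) or the string labels of
    the annotation dialect.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = _as_bool_labels(labels)
    if len(X) < 20:
        raise InsufficientDataError(f"{len(X)} samples < 20")
    if not np.all(np.isfinite(X)):
        raise OsaprogError("non-finite features")
    if y.all() or not y.any():
        raise OsaprogError("both classes must be present")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / scale

    n_per_class = min(y.sum(), (~y).sum())
    folds = int(min(k_folds, n_per_class))
    sens, spec = [], []
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(Xs, y):
            clf = SVC(kernel="rbf", gamma=gamma, C=C).fit(Xs[tr], y[tr])
            pred = clf.predict(Xs[te])
            tp = np.sum(pred & y[te]); fn = np.sum(~pred & y[te])
            tn = np.sum(~pred & ~y[te]); fp = np.sum(pred & ~y[te])
            if tp + fn:
                sens.append(tp / (tp + fn))
            if tn + fp:
                spec.append(tn / (tn + fp))
    svc = SVC(kernel="rbf", gamma=gamma, C=C).fit(Xs, y)
    part = ApneaPartition(svc, mean, scale,
                          float(np.mean(sens)) if sens else float("nan"),
                          float(np.mean(spec)) if spec else float("nan"),
                          int(svc.n_support_.sum()))
    logger.info("partition trained: CV sensitivity %.3f specificity %.3f, "
                "%d support vectors", part.cv_sensitivity, part.cv_specificity,
                part.n_support)
    return part


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return np.array([lab == APNEA for lab in labels])


# ---------------------------------------------------------------------------
# Collapsed Gibbs sampling for the DP Gaussian mixture
# ---------------------------------------------------------------------------

class _NIWCluster:
    """Sufficient statistics + cached posterior Cholesky for one cluster."""

    __slots__ = ("n", "sum", "scatter", "_chol", "_params")

    def __init__(self, d: int):
        self.n = 0
        self.sum = np.zeros(d)
        self.scatter = np.zeros((d, d))
        self._chol = None
        self._params = None

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        self.sum += x
        self.scatter += np.outer(x, x)
        self._chol = None

    def remove(self, x: np.ndarray) -> None:
        self.n -= 1
        self.sum -= x
        self.scatter -= np.outer(x, x)
        self._chol = None

    def posterior_predictive_params(self, prior) -> tuple:
        """(mu_n, chol of t-scale matrix, dof) of the Student-t predictive."""
        if self._chol is not None:
            return self._params
        mu0, kappa0, nu0, psi0 = prior
        d = len(mu0)
        n = self.n
        kappa_n = kappa0 + n
        nu_n = nu0 + n
        mu_n = (kappa0 * mu0 + self.sum) / kappa_n
        if n > 0:
            mean = self.sum / n
            S = self.scatter - np.outer(self.sum, mean)
            psi_n = psi0 + S + (kappa0 * n / kappa_n) * np.outer(mean - mu0, mean - mu0)
        else:
            psi_n = psi0.copy()
        dof = nu_n - d + 1
        scale = psi_n * (kappa_n + 1) / (kappa_n * dof)
        scale = (scale + scale.T) / 2.0
        try:
            L = cholesky(scale, lower=True)
        except np.linalg.LinAlgError:
            L = cholesky(scale + 1e-9 * np.eye(d), lower=True)
        self._params = (mu_n, L, dof)
        self._chol = L
        return self._params


def _t_logpdf(x: np.ndarray, mu: np.ndarray, L: np.ndarray, dof: float) -> float:
    d = len(x)
    z = solve_triangular(L, x - mu, lower=True)
    maha = float(z @ z)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(gammaln((dof + d) / 2) - gammaln(dof / 2)
                 - 0.5 * (d * np.log(dof * np.pi) + logdet)
                 - 0.5 * (dof + d) * np.log1p(maha / dof))


@dataclass
class _LocalGP:
    """A cluster's GP with its leave-one-out residual covariance.

    GPs fitted on a handful of points interpolate their training data
    and report near-zero predictive variance even when the one-step
    dynamics are genuinely stochastic (e.g. occasional jumps between
    physiological regimes).  The covariance of the leave-one-out
    residual vectors is an honest small-sample estimate of that
    irreducible noise — including its cross-dimension correlation, which
    a shared-kernel GP cannot represent — and is added to the GP's own
    predictive variance.
    """

    gp: GaussianProcessRegressor
    loo_cov: np.ndarray


@dataclass
class DPMGModel:
    """Posterior clustering of states plus per-cluster local GP forecasters."""

    states: np.ndarray
    successors: np.ndarray
    assignments: np.ndarray              # modal cluster id per training state
    alpha: float
    prior: tuple                         # (mu0, kappa0, nu0, psi0)
    gps: dict[int, _LocalGP] = field(default_factory=dict)
    gp_y_dim: int = 0
    fallback_mean: np.ndarray | None = None
    fallback_cov: np.ndarray | None = None
    seed: int = 0

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.assignments)

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.assignments, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def assign_cluster(self, x: np.ndarray) -> int:
        """Cluster maximizing the DP posterior predictive membership.

        Weight of cluster k is its size; the density is the NIW
        posterior-predictive Student-t of that cluster.  No new cluster
        is opened at prediction time, so assignment is total.
        """
        x = np.asarray(x, float).ravel()
        if not np.all(np.isfinite(x)):
            raise OsaprogError("non-finite query state")
        best, best_lp = -1, -np.inf
        for k in self.cluster_ids:
            members = self.states[self.assignments == k]
            cl = _NIWCluster(len(x))
            cl.n = len(members)
            cl.sum = members.sum(axis=0)
            cl.scatter = members.T @ members
            mu, L, dof = cl.posterior_predictive_params(self.prior)
            lp = np.log(cl.n) + _t_logpdf(x, mu, L, dof)
            if lp > best_lp:
                best, best_lp = int(k), lp
        return best

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian predictive (mean, covariance) of the next state."""
        x = np.asarray(x, float).ravel()
        k = self.assign_cluster(x)
        if k in self.gps:
            local = self.gps[k]
            mean, std = local.gp.predict(x[None, :], return_std=True)
            mean = np.atleast_1d(mean.ravel())
            std = np.atleast_1d(std).ravel()
            if len(std) == 1 and len(mean) > 1:
                std = np.repeat(std, len(mean))
            return mean, np.diag(std ** 2) + local.loo_cov
        return self.fallback_mean.copy(), self.fallback_cov.copy()


def _gibbs_dp_gaussian(X: np.ndarray, alpha: float, n_iter: int,
                       rng: np.random.Generator,
                       prior: tuple) -> np.ndarray:
    """Collapsed Gibbs for the DP Gaussian mixture; returns the modal partition.

    The modal partition is the canonicalized assignment vector visited
    most often over the second half of the sweeps.
    """
    n, d = X.shape
    # singleton initialization: single-site Gibbs merges clusters easily
    # but splits them very slowly, so start fully split
    z = np.arange(n, dtype=int)
    clusters: dict[int, _NIWCluster] = {}
    for i, x in enumerate(X):
        clusters[i] = _NIWCluster(d)
        clusters[i].add(x)
    next_id = n
    partition_counts: dict[tuple, int] = {}
    partition_repr: dict[tuple, np.ndarray] = {}
    prior_pred = _NIWCluster(d).posterior_predictive_params(prior)
    log_alpha = np.log(alpha)

    for sweep in range(n_iter):
        for i in range(n):
            x = X[i]
            k_old = z[i]
            clusters[k_old].remove(x)
            if clusters[k_old].n == 0:
                del clusters[k_old]
            ids = list(clusters.keys())
            logp = np.empty(len(ids) + 1)
            for j, k in enumerate(ids):
                cl = clusters[k]
                mu, L, dof = cl.posterior_predictive_params(prior)
                logp[j] = np.log(cl.n) + _t_logpdf(x, mu, L, dof)
            mu, L, dof = prior_pred
            logp[-1] = log_alpha + _t_logpdf(x, mu, L, dof)
            p = np.exp(logp - logp.max())
            p /= p.sum()
            choice = rng.choice(len(p), p=p)
            if choice == len(ids):
                k_new = next_id
                next_id += 1
                clusters[k_new] = _NIWCluster(d)
            else:
                k_new = ids[choice]
            clusters[k_new].add(x)
            z[i] = k_new
        if sweep >= n_iter // 2:
            key = _canonical_partition(z)
            partition_counts[key] = partition_counts.get(key, 0) + 1
            if key not in partition_repr:
                partition_repr[key] = z.copy()
    modal_key = max(partition_counts, key=partition_counts.get)
    return _relabel(partition_repr[modal_key])


def _canonical_partition(z: np.ndarray) -> tuple:
    seen: dict[int, int] = {}
    out = []
    for k in z:
        if k not in seen:
            seen[k] = len(seen)
        out.append(seen[k])
    return tuple(out)


def _relabel(z: np.ndarray) -> np.ndarray:
    return np.array(_canonical_partition(z), dtype=int)


def fit_dpmg(states: np.ndarray, successors: np.ndarray | None = None,
             alpha: float = 1.0, seed: int = 0, n_iter: int = 500,
             fit_gps: bool = True) -> DPMGModel:
    """Fit the DPMG: collapsed-Gibbs DP clustering + local GPs per cluster.

    Parameters
    ----------
    states
        (n, d) embedded state vectors x_t, or an
        :class:`~osaprog.embedding.EmbeddedStates` (successor pairs are
        then derived from consecutive minutes).
    successors
        (n, d) one-step successors x_{t+1}; required for GP fitting when
        ``states`` is a plain array.
    alpha
        DP concentration.
    n_iter
        Gibbs sweeps; the modal partition over the second half defines
        the clusters.
    """
    from .embedding import EmbeddedStates

    if isinstance(states, EmbeddedStates):
        X, Y = states.successor_pairs()
    else:
        X = np.atleast_2d(np.asarray(states, float))
        Y = None if successors is None else np.atleast_2d(np.asarray(successors, float))
    if len(X) < 30:
        raise InsufficientDataError(f"{len(X)} states < 30")
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    mu0 = X.mean(axis=0)
    var = X.var(axis=0)
    psi0 = np.diag(np.where(var > 0, var, 1.0))
    prior = (mu0, 0.1, float(d + 2), psi0)
    z = _gibbs_dp_gaussian(X, alpha, n_iter, rng, prior)
    model = DPMGModel(X, Y if Y is not None else np.empty((0, d)),
                      z, alpha, prior, seed=seed)

    if fit_gps and Y is not None and len(Y) == len(X):
        model.fallback_mean = Y.mean(axis=0)
        fb_cov = np.atleast_2d(np.cov(Y.T)) if len(Y) > 1 else np.eye(Y.shape[1])
        # inflate: the fallback ignores the current state entirely
        model.fallback_cov = 2.0 * fb_cov + 1e-9 * np.eye(Y.shape[1])
        model.gp_y_dim = Y.shape[1]
        for k, size in model.cluster_sizes().items():
            if size < MIN_CLUSTER_FOR_GP:
                logger.info("cluster %d (%d members): global-mean fallback", k, size)
                continue
            mask = z == k
            model.gps[k] = _fit_local_gp(X[mask], Y[mask], seed)
    return model


def _fit_local_gp(Xk: np.ndarray, Yk: np.ndarray, seed: int) -> _LocalGP:
    """Squared-exponential + white-noise GP, hyperparameters by ML-II."""
    scale = float(np.mean(Xk.std(axis=0))) or 1.0
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=scale, length_scale_bounds=(1e-3 * scale, 1e3 * scale))
              + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-10, 1e1)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=1, random_state=seed)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(Xk, Yk)
    return _LocalGP(gp, _gp_loo_residual_cov(gp, Yk))


def _gp_loo_residual_cov(gp: GaussianProcessRegressor, Yk: np.ndarray) -> np.ndarray:
    """Leave-one-out residual covariance matrix of a fitted GP.

    Closed form from the fitted Cholesky factor: the LOO residual of
    point i is ``alpha_i / [K^{-1}]_{ii}`` (Sundararajan–Keerthi),
    rescaled back from the normalized-target space; the residual
    vectors' second-moment matrix estimates the irreducible one-step
    noise including its cross-dimension correlation.
    """
    L = gp.L_
    n = L.shape[0]
    Kinv = solve_triangular(L.T, solve_triangular(L, np.eye(n), lower=True),
                            lower=False)
    diag = np.clip(np.diag(Kinv), 1e-12, None)
    alpha = np.atleast_2d(gp.alpha_)
    if alpha.shape[0] != n:
        alpha = alpha.T
    resid = alpha / diag[:, None]
    y_std = np.atleast_1d(getattr(gp, "_y_train_std", 1.0))
    resid = resid * y_std[None, :]
    d = Yk.shape[1] if Yk.ndim == 2 else 1
    if resid.shape[1] != d:
        resid = np.repeat(resid, d, axis=1)
    return (resid.T @ resid) / n


def lgp_predict(model: DPMGModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean vector and covariance of the next state at ``x``.

    Thin functional wrapper over :meth:`DPMGModel.predict`: the query is
    assigned to the cluster with maximal posterior membership and that
    cluster's local GP supplies the Gaussian predictive law.
    """
    return model.predict(x)
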