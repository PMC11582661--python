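"""Panel-data likelihood of the multi-state model, with analytic score.

For panel observations the likelihood of one individual is a product over
consecutive sightings (state ``a`` at ``t``, state ``b`` at ``t + dt``) of
``P_ab(dt | z) = [expm(dt Q(z))]_ab``.  A death observed at an exact date
contributes ``sum_m P_am(dt) q_m7`` instead: the individual was in some live
state ``m`` just before dying at the recorded day.  Follow-up that simply
ends in a live state contributes nothing further (non-informative
right-censoring).

Two routes are provided:

* a plain per-individual reference (`individual_log_likelihood`) built on
  scipy's ``expm`` — transparent, used for cross-checks;
* a batched engine (`PanelLikelihood`) that evaluates the total
  log-likelihood and its exact gradient for all individuals at once via
  eigendecomposition of each individual's generator.  The gradient uses the
  Daleckii-Krein divided-difference form of the Frechet derivative of the
  matrix exponential (the classic approach for panel multi-state models);
  individuals whose generator is numerically non-diagonalizable fall back to
  ``expm`` / ``expm_frechet``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import expm, expm_frechet

from .data import PanelDataset
from .states import DEATH, N_STATES, ModelParameters, TransitionStructure

_TINY = 1e-300
_ETA_CAP = 30.0  # log-intensity guard: caps rates at ~1e13/day before exp


# ---------------------------------------------------------------------------
# reference route
# ---------------------------------------------------------------------------

def individual_log_likelihood(times, states, params: ModelParameters, z=None,
                              death_exact: bool = True) -> float:
    """Log-likelihood contribution of one individual's observation sequence.

    Parameters
    ----------
    times, states : sequences
        Observation days (strictly increasing) and state codes 1-7.
    params : ModelParameters
    z : CovariateVector, optional
    death_exact : bool
        If True, a terminal death record is treated as an exactly dated
        event; otherwise death is handled like any panel observation.
    """
    from .states import intensity_matrix

    times = np.asarray(times, float)
    states = np.asarray(states, int)
    if len(times) != len(states) or len(times) == 0:
        raise ValueError("need equally many times and states, at least one record")
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must strictly increase")
    if np.any(states[:-1] == DEATH):
        raise ValueError("death may appear only as the final record")

    q = intensity_matrix(params, z).q
    ll = 0.0
    for (t0, a), (t1, b) in zip(zip(times[:-1], states[:-1]), zip(times[1:], states[1:])):
        dt = t1 - t0
        if b != a and b not in params.structure.reachable_from(a):
            warnings.warn(
                f"state {b} is unreachable from state {a} under the transition "
                "structure; contribution is -inf"
            )
            return -np.inf
        p = expm(q * dt)
        if b == DEATH and death_exact:
            lik = float(p[a - 1, :] @ q[:, DEATH - 1])
        else:
            lik = float(p[a - 1, b - 1])
        ll += np.log(max(lik, _TINY))
    return ll


def total_log_likelihood(data: PanelDataset, params: ModelParameters,
                         death_exact: bool = True) -> float:
    """Sum of individual contributions over a stratum (reference route)."""
    from .covariates import CovariateVector

    if len(data.records) == 0:
        raise ValueError("no likelihood defined for an empty dataset")
    ll = 0.0
    for ind, g in data.individuals():
        first = g.iloc[0]
        z = CovariateVector(
            slum_area=first["slum_area"],
            ethnicity=first["ethnicity"],
            area_of_birth=first["area_of_birth"],
            age=float(first["age"]),
        )
        try:
            ll += individual_log_likelihood(
                g["time_days"].to_numpy(), g["state"].to_numpy(),
                params, z, death_exact,
            )
        except ValueError as exc:
            raise ValueError(f"individual {ind!r}: {exc}") from exc
    return ll


# ---------------------------------------------------------------------------
# batched engine
# ---------------------------------------------------------------------------

class PanelLikelihood:
    """Batched total log-likelihood and exact score for one stratum.

    Flattens a :class:`PanelDataset` into arrays once; each call to
    :meth:`value_and_grad` evaluates all individuals simultaneously.

    Parameter vector layout: ``theta = [alpha_1..alpha_K, vec(beta)]`` with
    ``beta`` stored row-major as ``(n_terms, K)`` for the K allowed
    transitions in structure order.
    """

    def __init__(self, data: PanelDataset, structure: TransitionStructure,
                 terms=(), death_exact: bool = True, chunk: int = 20000):
        from .covariates import design_matrix

        self.structure = structure
        self.terms = tuple(terms)
        self.death_exact = bool(death_exact)
        self.K = len(structure)
        self.chunk = int(chunk)
        self.i_idx = np.array([i - 1 for i, _ in structure.allowed])
        self.j_idx = np.array([j - 1 for _, j in structure.allowed])

        df = data.records
        ids, ind_of_row = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
        self.n_ind = len(ids)
        order = np.lexsort((df["time_days"].to_numpy(float), ind_of_row))
        ind_s = ind_of_row[order]
        t_s = df["time_days"].to_numpy(float)[order]
        s_s = df["state"].to_numpy(int)[order]

        same = ind_s[1:] == ind_s[:-1]
        self.p_ind = ind_s[1:][same]
        self.p_a = s_s[:-1][same] - 1
        self.p_b = s_s[1:][same] - 1
        self.p_dt = (t_s[1:] - t_s[:-1])[same]
        self.p_death = (self.p_b == DEATH - 1) & self.death_exact
        self.n_pairs = len(self.p_dt)

        reach = {a: structure.reachable_from(a) for a in range(1, N_STATES + 1)}
        for a, b in zip(self.p_a, self.p_b):
            if b != a and (b + 1) not in reach[a + 1]:
                raise ValueError(
                    f"observed pair {a + 1}->{b + 1} is unreachable under the "
                    "transition structure"
                )

        # one covariate row per individual, taken at its first observation
        idx_first = np.zeros(self.n_ind, dtype=int)
        seen = np.zeros(self.n_ind, dtype=bool)
        for pos, ind in enumerate(ind_s):
            if not seen[ind]:
                idx_first[ind] = order[pos]
                seen[ind] = True
        roster = df.iloc[idx_first]
        X = design_matrix(roster, self.terms)  # (n_ind, n_terms)
        self.n_terms = X.shape[1]
        self.n_params = self.K * (1 + self.n_terms)
        # optimize on unit-scale columns (the age column is O(50) and would
        # otherwise wreck the conditioning); theta stays in scaled units and
        # is mapped back by to_natural / from_natural
        self.col_scale = np.maximum(X.std(axis=0), 1.0) if len(X) else \
            np.ones(self.n_terms)
        self.X = X / self.col_scale

        # crude-rate sufficient statistics for initialization
        self._time_in_state = np.zeros(N_STATES)
        np.add.at(self._time_in_state, self.p_a, self.p_dt)
        self._direct_counts = np.zeros(self.K)
        pair_index = {p: k for k, p in enumerate(structure.allowed)}
        for a, b in zip(self.p_a, self.p_b):
            k = pair_index.get((a + 1, b + 1))
            if k is not None:
                self._direct_counts[k] += 1

    # -- parameter helpers -------------------------------------------------
    def unpack(self, theta):
        theta = np.asarray(theta, float)
        alpha = theta[: self.K]
        beta = theta[self.K:].reshape(self.n_terms, self.K)
        return alpha, beta

    def pack(self, alpha, beta=None):
        if beta is None:
            beta = np.zeros((self.n_terms, self.K))
        return np.concatenate([np.asarray(alpha, float), np.asarray(beta, float).ravel()])

    def initial_theta(self, floor: float = 1e-6):
        """Crude-rate start: q0 = direct transitions / time at risk, floored."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self._direct_counts / self._time_in_state[self.i_idx]
        rates = np.where(np.isfinite(rates), rates, 0.0)
        return self.pack(np.log(np.maximum(rates, floor)))

    def to_natural(self, theta) -> np.ndarray:
        """Map engine-scale theta to natural units (beta per raw covariate)."""
        alpha, beta = self.unpack(theta)
        return self.pack(alpha, beta / self.col_scale[:, None])

    def from_natural(self, theta_nat) -> np.ndarray:
        alpha, beta = self.unpack(theta_nat)
        return self.pack(alpha, beta * self.col_scale[:, None])

    def natural_scale_vector(self) -> np.ndarray:
        """d(natural theta)/d(engine theta), diagonal (for covariances)."""
        d = np.ones(self.n_params)
        d[self.K:] = np.repeat(1.0 / self.col_scale, self.K)
        return d

    def params_from_theta(self, theta) -> ModelParameters:
        alpha, beta = self.unpack(self.to_natural(theta))
        return ModelParameters.from_arrays(self.structure, alpha, beta, self.terms)

    # -- core evaluation ---------------------------------------------------
    def _generators(self, theta):
        alpha, beta = self.unpack(theta)
        eta = alpha[None, :] + self.X @ beta
        R = np.exp(np.minimum(eta, _ETA_CAP))  # (n_ind, K)
        Q = np.zeros((self.n_ind, N_STATES, N_STATES))
        Q[:, self.i_idx, self.j_idx] = R
        Q[:, np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=2)
        return R, Q

    def value_and_grad(self, theta):
        """Total log-likelihood and its gradient in theta."""
        R, Q = self._generators(theta)
        w, V = np.linalg.eig(Q)
        ok = np.zeros(self.n_ind, dtype=bool)
        Vinv = np.empty_like(V)
        cond = np.full(self.n_ind, np.inf)
        try:
            Vinv = np.linalg.inv(V)
            with np.errstate(over="ignore"):
                cond = (np.abs(V).sum(axis=(1, 2)) * np.abs(Vinv).sum(axis=(1, 2)))
            ok = np.isfinite(cond) & (cond < 1e12)
        except np.linalg.LinAlgError:
            for i in range(self.n_ind):
                try:
                    Vinv[i] = np.linalg.inv(V[i])
                    ok[i] = np.abs(V[i]).sum() * np.abs(Vinv[i]).sum() < 1e12
                except np.linalg.LinAlgError:
                    ok[i] = False

        ll = 0.0
        M = np.zeros((self.n_pairs, self.K))
        fast = ok[self.p_ind]
        ll += self._fast_block(np.flatnonzero(fast), w, V, Vinv, Q, M)
        slow_idx = np.flatnonzero(~fast)
        if len(slow_idx):
            ll += self._slow_block(slow_idx, Q, M)

        Mw = M * R[self.p_ind]  # chain rule through r_k = exp(eta_k)
        g_alpha = Mw.sum(axis=0)
        g_beta = self.X[self.p_ind].T @ Mw
        return ll, np.concatenate([g_alpha, g_beta.ravel()])

    def value(self, theta):
        return self.value_and_grad(theta)[0]

    def _fast_block(self, sl, w, V, Vinv, Q, M):
        """Eigendecomposition route for pair indices ``sl``; fills score in M.

        Works per unique (individual, interval length): with regular survey
        rounds most pairs of one individual share the same interval, so the
        full ``P`` and ``dP/dr_k`` matrices are computed once per combination
        and gathered per pair.
        """
        if len(sl) == 0:
            return 0.0
        ind = self.p_ind[sl]
        dt = self.p_dt[sl]
        keys = np.stack(
            [ind.astype(np.int64), np.ascontiguousarray(dt).view(np.int64)],
            axis=1)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        u_ind = np.ascontiguousarray(uniq[:, 0])
        u_dt = np.ascontiguousarray(uniq[:, 1]).view(np.float64)
        ll = 0.0
        for ustart in range(0, len(uniq), self.chunk):
            ustop = min(ustart + self.chunk, len(uniq))
            in_block = (inv >= ustart) & (inv < ustop)
            ll += self._fast_unique_block(
                sl[in_block], inv[in_block] - ustart,
                u_ind[ustart:ustop], u_dt[ustart:ustop],
                w, V, Vinv, Q, M)
        return ll

    def _fast_unique_block(self, psel, uidx, uind, udt, w, V, Vinv, Q, M):
        K = self.K
        wv = w[uind]                            # (U,7) complex
        Ew = np.exp(wv * udt[:, None])
        Vu = V[uind]
        Viu = Vinv[uind]
        Pfull = np.real((Vu * Ew[:, None, :]) @ Viu)          # (U,7,7)

        # divided differences Phi_ml = (e^{t wm} - e^{t wl})/(wm - wl);
        # when the (dimensionless) eigenvalue gap t|wm - wl| is tiny the
        # quotient cancels catastrophically, so switch to the confluent
        # limit t e^{t(wm+wl)/2} (relative error O((t dw)^2/12))
        t_ = udt[:, None, None]
        dw = wv[:, :, None] - wv[:, None, :]
        num = Ew[:, :, None] - Ew[:, None, :]
        small = np.abs(dw) * np.abs(t_) < 1e-5
        with np.errstate(divide="ignore", invalid="ignore"):
            Phi = num / np.where(small, 1.0, dw)
        mid = np.exp(0.5 * (wv[:, :, None] + wv[:, None, :]) * t_)
        Phi = np.where(small, t_ * mid, Phi)

        # dP/dr_k = V (Phi o (Vinv e_i) (e_j - e_i)' V) Vinv, rank-1 inner part
        Ai = np.transpose(Viu[:, :, self.i_idx], (0, 2, 1))   # (U,K,7)
        Dj = Vu[:, self.j_idx, :] - Vu[:, self.i_idx, :]      # (U,K,7)
        G = Phi[:, None, :, :] * (Ai[:, :, :, None] * Dj[:, :, None, :])
        dP = np.real(Vu[:, None, :, :] @ G @ Viu[:, None, :, :])  # (U,K,7,7)

        a = self.p_a[psel]
        b = self.p_b[psel]
        death = self.p_death[psel]
        live = ~death
        pval = np.empty(len(psel))
        C = np.empty((len(psel), K))
        pval[live] = Pfull[uidx[live], a[live], b[live]]
        C[live] = dP[uidx[live], :, a[live], b[live]]
        if death.any():
            d = np.flatnonzero(death)
            q7 = Q[self.p_ind[psel[d]], :, DEATH - 1]          # (D,7)
            Prow = Pfull[uidx[d], a[d], :]                    # (D,7)
            pval[d] = np.einsum("dm,dm->d", Prow, q7)
            C[d] = np.einsum("dkm,dm->dk", dP[uidx[d], :, a[d], :], q7)
            C[d] += Prow[:, self.i_idx] * (self.j_idx == DEATH - 1)[None, :]

        pval = np.maximum(pval, _TINY)
        M[psel] = C / pval[:, None]
        return float(np.log(pval).sum())

    def _slow_block(self, sl, Q, M):
        """expm / expm_frechet fallback for numerically defective generators."""
        ll = 0.0
        Ek = np.zeros((self.K, N_STATES, N_STATES))
        Ek[np.arange(self.K), self.i_idx, self.j_idx] = 1.0
        Ek[np.arange(self.K), self.i_idx, self.i_idx] = -1.0
        for p in sl:
            ind, a, b, dt = self.p_ind[p], self.p_a[p], self.p_b[p], self.p_dt[p]
            q = Q[ind]
            P = expm(q * dt)
            if self.p_death[p]:
                val = float(P[a, :] @ q[:, DEATH - 1])
            else:
                val = float(P[a, b])
            val = max(val, _TINY)
            ll += np.log(val)
            for k in range(self.K):
                _, F = expm_frechet(q * dt, Ek[k] * dt)
                if self.p_death[p]:
                    d = float(F[a, :] @ q[:, DEATH - 1])
                    if self.j_idx[k] == DEATH - 1:
                        d += float(P[a, self.i_idx[k]])
                else:
                    d = float(F[a, b])
                M[p, k] = d / val
        return ll
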