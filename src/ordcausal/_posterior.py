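"""Log posterior density and analytic gradient for the multilevel
cumulative-logit model.

Parameterization (unconstrained vector, in order):

* ``c``        — first cutpoint plus log-increments (K-1 values)
* ``beta``     — population coefficients: sex, food, education, age, children
* ``y_edu``    — stick-breaking coordinates of the education simplex (D_E - 1)
* ``y_age``    — likewise for age (D_A - 1)
* ``y_child``  — likewise for children (D_C - 1)
* ``s``        — log standard deviations of the six site-varying effects
* ``w``        — atanh canonical partial correlations of the 6x6 site-effect
                 correlation matrix (15 values, row-major lower triangle)
* ``Z``        — non-centred standard-normal site effect innovations (6 x S)

Priors: cutpoints Normal(0, threshold_scale); coefficients
Normal(0, coef_scale); simplexes Dirichlet(alpha, ..., alpha); SDs
Exponential(sd_rate); correlation LKJ(lkj_shape).  The LKJ prior combined
with the tanh transform makes each partial correlation an independent
scaled Beta, which is used both here and in the prior sampler.

All gradients are analytic and are verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

J_EFFECTS = 6  # intercept + five coefficients vary by site

_TINY = 1e-300


def _reverse_cumsum(x, axis=-1):
    return np.flip(np.cumsum(np.flip(x, axis=axis), axis=axis), axis=axis)


def stick_breaking_offsets(d: int) -> np.ndarray:
    """Offsets making y = 0 map to the uniform simplex (length d-1)."""
    t = np.arange(1, d)
    return -np.log(d - t)


def simplex_from_unconstrained(y: np.ndarray, d: int) -> np.ndarray:
    """Map unconstrained coordinates (..., d-1) to simplex points (..., d)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if d == 1:
        return np.ones(y.shape[:-1] + (1,))
    z = np.clip(expit(y + stick_breaking_offsets(d)), 1e-15, 1 - 1e-15)
    cp = np.cumprod(1.0 - z, axis=-1)
    head = np.concatenate(
        [np.ones_like(cp[..., :1]), cp[..., :-1]], axis=-1
    )
    return np.concatenate([z * head, cp[..., -1:]], axis=-1)


def lkj_cpc_shapes(j: int, eta: float) -> np.ndarray:
    """Beta shapes of the canonical partial correlations under LKJ(eta).

    Row-major lower-triangle ordering: pair (i, col) has shape
    eta + (j - 2 - col) / 2, depending only on the column.
    """
    shapes = []
    for i in range(1, j):
        for col in range(i):
            shapes.append(eta + (j - 2 - col) / 2.0)
    return np.array(shapes)


def cholesky_from_cpc(z: np.ndarray, j: int) -> np.ndarray:
    """Build the correlation Cholesky factor from partial correlations.

    ``z`` may have leading batch dimensions; last axis is j*(j-1)/2.
    """
    z = np.asarray(z, dtype=float)
    batch = z.shape[:-1]
    L = np.zeros(batch + (j, j))
    L[..., 0, 0] = 1.0
    idx = 0
    for i in range(1, j):
        rem = np.ones(batch)
        for col in range(i):
            zc = z[..., idx]
            idx += 1
            L[..., i, col] = zc * np.sqrt(rem)
            rem = rem * (1.0 - zc**2)
        L[..., i, i] = np.sqrt(rem)
    return L


class DesignData:
    """Validated, integer-coded arrays for one outcome's fit."""

    def __init__(self, *, site_idx, sex, food, edu, age_idx, child, outcome,
                 n_sites, sites):
        self.site_idx = np.asarray(site_idx, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=float)
        self.food = np.asarray(food, dtype=float)
        self.edu = np.asarray(edu, dtype=np.int64)
        self.age_idx = np.asarray(age_idx, dtype=np.int64)
        self.child = np.asarray(child, dtype=np.int64)
        self.outcome = np.asarray(outcome, dtype=np.int64)
        self.n_sites = int(n_sites)
        self.sites = tuple(sites)
        self.n = self.site_idx.size


class OrdinalPosterior:
    """Value-and-gradient oracle for the joint log posterior."""

    def __init__(self, design: DesignData, spec) -> None:
        self.design = design
        self.spec = spec
        self.K = spec.n_categories
        self.DE = spec.d_education
        self.DA = spec.d_age
        self.DC = spec.d_children
        self.S = design.n_sites
        self.J = J_EFFECTS

        self.ts2 = spec.threshold_scale**2
        self.cs2 = spec.coef_scale**2
        self.alpha = spec.dirichlet_alpha
        self.sd_rate = spec.sd_rate
        self.lkj_a = lkj_cpc_shapes(self.J, spec.lkj_shape)

        self.offE = stick_breaking_offsets(self.DE)
        self.offA = stick_breaking_offsets(self.DA)
        self.offC = stick_breaking_offsets(self.DC)

        K = self.K
        y = design.outcome
        self.has_upper = y <= K - 1
        self.has_lower = y >= 2
        self.up_idx = np.clip(y - 1, 0, K - 2)
        self.lo_idx = np.clip(y - 2, 0, K - 2)

        # Fused-bincount scaffolding: fixed index arrays reused every eval.
        n = design.n
        S = self.S
        self._site6 = np.concatenate(
            [design.site_idx + jj * S for jj in range(J_EFFECTS)]
        )
        self._xstack = np.empty((J_EFFECTS, n))
        self._xstack[0] = 1.0
        self._xstack[1] = design.sex
        self._xstack[2] = design.food
        self._mo_levels = np.concatenate(
            [
                design.edu,
                (self.DE + 1) + design.age_idx,
                (self.DE + 1) + (self.DA + 1) + design.child,
            ]
        )
        self._mo_total = (self.DE + 1) + (self.DA + 1) + (self.DC + 1)

        try:
            from ._posterior_fast import HAVE_NUMBA

            self.use_fast = HAVE_NUMBA
        except ImportError:  # pragma: no cover
            self.use_fast = False

        n_corr = self.J * (self.J - 1) // 2
        sizes = [
            K - 1, 5, self.DE - 1, self.DA - 1, self.DC - 1,
            self.J, n_corr, self.J * self.S,
        ]
        bounds = np.cumsum([0] + sizes)
        names = ["c", "beta", "y_edu", "y_age", "y_child", "s", "w", "Z"]
        self.slices = {
            nm: slice(int(a), int(b))
            for nm, a, b in zip(names, bounds[:-1], bounds[1:])
        }
        self.dim = int(bounds[-1])

    # -- forward/backward pieces ------------------------------------------

    def _simplex_fwd(self, y, d, offsets):
        if d == 1:
            return np.array([1.0]), None, None, 0.0
        z = np.clip(expit(y + offsets), 1e-15, 1 - 1e-15)
        onemz = 1.0 - z
        cp = np.cumprod(onemz)
        zeta = np.empty(d)
        zeta[0] = z[0]
        if d > 2:
            zeta[1:d - 1] = z[1:] * cp[:-1]
        zeta[d - 1] = cp[-1]
        t = np.arange(1, d)
        logp = (self.alpha - 1.0) * np.sum(np.log(zeta)) + np.sum(
            np.log(z) + (d - t) * np.log(onemz)
        )
        return zeta, z, cp, logp

    def _simplex_bwd(self, g_zeta, zeta, z, cp, d):
        if d == 1:
            return np.zeros(0)
        g_zeta = g_zeta + (self.alpha - 1.0) / zeta
        w = g_zeta * zeta
        tail = _reverse_cumsum(w)
        cp_prev = np.concatenate(([1.0], cp[:-1]))
        onemz = 1.0 - z
        g_z = g_zeta[: d - 1] * cp_prev - tail[1:] / onemz
        t = np.arange(1, d)
        g_z = g_z + 1.0 / z - (d - t) / onemz
        return g_z * z * onemz

    def _chol_fwd(self, zc):
        j = self.J
        L = np.zeros((j, j))
        L[0, 0] = 1.0
        rems = []
        idx = 0
        for i in range(1, j):
            zi = zc[idx: idx + i]
            idx += i
            rem = np.empty(i + 1)
            rem[0] = 1.0
            for col in range(i):
                L[i, col] = zi[col] * np.sqrt(rem[col])
                rem[col + 1] = rem[col] * (1.0 - zi[col] ** 2)
            L[i, i] = np.sqrt(rem[i])
            rems.append(rem)
        return L, rems

    def _chol_bwd(self, g_L, zc, rems):
        j = self.J
        parts = []
        idx = 0
        for i in range(1, j):
            zi = zc[idx: idx + i]
            idx += i
            rem = rems[i - 1]
            g_zi = np.zeros(i)
            g_rem_next = g_L[i, i] * 0.5 / np.sqrt(rem[i])
            for col in range(i - 1, -1, -1):
                sq = np.sqrt(rem[col])
                g_zi[col] = (
                    g_L[i, col] * sq - 2.0 * zi[col] * rem[col] * g_rem_next
                )
                g_rem_next = (
                    g_L[i, col] * zi[col] * 0.5 / sq
                    + g_rem_next * (1.0 - zi[col] ** 2)
                )
            parts.append(g_zi)
        return np.concatenate(parts)

    # -- main entry point --------------------------------------------------

    def value_and_grad(self, theta):
        """Log posterior and gradient; uses the numba kernel when available."""
        if self.use_fast:
            from ._posterior_fast import logp_grad_kernel

            d = self.design
            grad = np.empty(self.dim)
            lp = logp_grad_kernel(
                np.ascontiguousarray(theta, dtype=float), grad,
                d.site_idx, d.sex, d.food, d.edu, d.age_idx, d.child,
                d.outcome, self.S, self.K, self.DE, self.DA, self.DC,
                self.ts2, self.cs2, self.alpha, self.sd_rate, self.lkj_a,
            )
            return float(lp), grad
        with np.errstate(all="ignore"):
            return self._value_and_grad(theta)

    def _value_and_grad(self, theta):
        d = self.design
        sl = self.slices
        K, S, J = self.K, self.S, self.J

        c = theta[sl["c"]]
        beta = theta[sl["beta"]]
        yE = theta[sl["y_edu"]]
        yA = theta[sl["y_age"]]
        yC = theta[sl["y_child"]]
        s = theta[sl["s"]]
        w = theta[sl["w"]]
        Z = theta[sl["Z"]].reshape(J, S)

        # cutpoints: kappa_1 = c_0, kappa_j = kappa_{j-1} + exp(c_j)
        ek = np.exp(c[1:])
        kappa = np.empty(K - 1)
        kappa[0] = c[0]
        kappa[1:] = c[0] + np.cumsum(ek)
        logp = -0.5 * np.sum(kappa**2) / self.ts2 + np.sum(c[1:])

        logp += -0.5 * np.sum(beta**2) / self.cs2

        zetaE, zE, cpE, lpE = self._simplex_fwd(yE, self.DE, self.offE)
        zetaA, zA, cpA, lpA = self._simplex_fwd(yA, self.DA, self.offA)
        zetaC, zC, cpC, lpC = self._simplex_fwd(yC, self.DC, self.offC)
        logp += lpE + lpA + lpC

        sigma = np.exp(s)
        logp += np.sum(-self.sd_rate * sigma + s)

        zc = np.tanh(w)
        logp += np.sum(self.lkj_a * np.log1p(-zc**2))
        L, rems = self._chol_fwd(zc)

        logp += -0.5 * np.sum(Z**2)
        A = sigma[:, None] * L
        U = A @ Z  # (J, S) site effects

        moE = self.DE * np.concatenate(([0.0], np.cumsum(zetaE)))
        moA = self.DA * np.concatenate(([0.0], np.cumsum(zetaA)))
        moC = self.DC * np.concatenate(([0.0], np.cumsum(zetaC)))

        xstack = self._xstack
        xstack[3] = moE[d.edu]
        xstack[4] = moA[d.age_idx]
        xstack[5] = moC[d.child]

        bfull = np.concatenate(([0.0], beta))
        B = bfull[:, None] + U  # (J, S)
        coefs = B[:, d.site_idx]  # (J, n)
        xi = np.einsum("jn,jn->n", xstack, coefs)

        hu = self.has_upper
        hl = self.has_lower
        e = expit(kappa[self.up_idx] - xi)
        p_hi = np.where(hu, e, 1.0)
        phi_hi = np.where(hu, e * (1.0 - e), 0.0)
        e2 = expit(kappa[self.lo_idx] - xi)
        p_lo = np.where(hl, e2, 0.0)
        phi_lo = np.where(hl, e2 * (1.0 - e2), 0.0)
        P = np.maximum(p_hi - p_lo, _TINY)
        logp += np.sum(np.log(P))

        if not np.isfinite(logp):
            return float("-inf"), np.zeros(self.dim)

        # ----- backward pass --------------------------------------------
        invP = 1.0 / P
        g_xi = (phi_lo - phi_hi) * invP

        g_kappa = np.bincount(
            self.up_idx, weights=phi_hi * invP, minlength=K - 1
        )
        g_kappa -= np.bincount(
            self.lo_idx, weights=phi_lo * invP, minlength=K - 1
        )
        g_kappa -= kappa / self.ts2
        rc = _reverse_cumsum(g_kappa)
        g_c = np.empty(K - 1)
        g_c[0] = rc[0]
        g_c[1:] = ek * rc[1:] + 1.0

        g_B = np.bincount(
            self._site6, weights=(xstack * g_xi).ravel(), minlength=J * S
        ).reshape(J, S)
        g_beta = g_B[1:].sum(axis=1) - beta / self.cs2
        g_U = g_B

        g_mo_all = np.bincount(
            self._mo_levels,
            weights=(coefs[3:6] * g_xi).ravel(),
            minlength=self._mo_total,
        )
        ofsA = self.DE + 1
        ofsC = ofsA + self.DA + 1
        g_yE = self._simplex_bwd(
            self.DE * _reverse_cumsum(g_mo_all[1:ofsA]),
            zetaE, zE, cpE, self.DE,
        )
        g_yA = self._simplex_bwd(
            self.DA * _reverse_cumsum(g_mo_all[ofsA + 1:ofsC]),
            zetaA, zA, cpA, self.DA,
        )
        g_yC = self._simplex_bwd(
            self.DC * _reverse_cumsum(g_mo_all[ofsC + 1:]),
            zetaC, zC, cpC, self.DC,
        )

        g_Z = A.T @ g_U - Z
        g_A = g_U @ Z.T
        g_sigma = np.sum(g_A * L, axis=1)
        g_s = g_sigma * sigma + (-self.sd_rate * sigma + 1.0)
        g_L = sigma[:, None] * g_A
        g_zc = self._chol_bwd(g_L, zc, rems)
        g_w = g_zc * (1.0 - zc**2) - 2.0 * self.lkj_a * zc

        grad = np.empty(self.dim)
        grad[sl["c"]] = g_c
        grad[sl["beta"]] = g_beta
        grad[sl["y_edu"]] = g_yE
        grad[sl["y_age"]] = g_yA
        grad[sl["y_child"]] = g_yC
        grad[sl["s"]] = g_s
        grad[sl["w"]] = g_w
        grad[sl["Z"]] = g_Z.ravel()
        return float(logp), grad

    # -- helpers for the sampler ------------------------------------------

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.dim)
        sl = self.slices
        c0 = np.zeros(self.K - 1)
        c0[0] = -1.5
        theta[sl["c"]] += c0
        theta[sl["s"]] += -1.0  # start with modest site-effect scales
        return theta

    def constrain(self, thetas: np.ndarray) -> dict:
        """Map a batch (m, dim) of unconstrained draws to model quantities."""
        thetas = np.atleast_2d(thetas)
        sl = self.slices
        m = thetas.shape[0]
        K, S, J = self.K, self.S, self.J

        c = thetas[:, sl["c"]]
        kappa = np.empty((m, K - 1))
        kappa[:, 0] = c[:, 0]
        kappa[:, 1:] = c[:, :1] + np.cumsum(np.exp(c[:, 1:]), axis=1)

        out = {
            "kappa": kappa,
            "beta": thetas[:, sl["beta"]].copy(),
            "zeta_edu": simplex_from_unconstrained(
                thetas[:, sl["y_edu"]], self.DE
            ),
            "zeta_age": simplex_from_unconstrained(
                thetas[:, sl["y_age"]], self.DA
            ),
            "zeta_children": simplex_from_unconstrained(
                thetas[:, sl["y_child"]], self.DC
            ),
            "sigma": np.exp(thetas[:, sl["s"]]),
        }
        zc = np.tanh(thetas[:, sl["w"]])
        L = cholesky_from_cpc(zc, J)
        out["corr"] = L @ np.swapaxes(L, -1, -2)
        Z = thetas[:, sl["Z"]].reshape(m, J, S)
        out["site_effects"] = (out["sigma"][:, :, None] * L) @ Z
        return out
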