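"""Posterior sampling for the hierarchical transition model.

The sampler is an adaptive Metropolis-within-Gibbs scheme: each scalar
parameter is updated in turn with a Gaussian random-walk proposal on an
unconstrained scale (logit for probabilities and for the bounded scale
and rate parameters, identity for regression coefficients and monthly
random effects), with the change-of-variables Jacobian folded into the
acceptance ratio so the target stays the posterior on the natural scale.
Proposal scales adapt toward a 0.44 acceptance rate during burn-in only,
preserving detailed balance for the retained draws.

Because the likelihood factorizes over strata, each component update
recomputes only the log-likelihood terms it can touch: a population's
(r, s) pair touches one (population, stage) slice of the monthly adult
strata, a monthly random effect touches one month of one stream, the
young-stage and recruitment parameters touch their own blocks.  The
count sub-arrays each component needs are extracted once up front so the
inner loop runs on small contiguous blocks.  Gap strata (transitions
spanning unsurveyed months) are evaluated with products of monthly
kernels and re-evaluated whenever a parameter of their population or
month span moves.

All randomness flows through one seeded ``numpy`` Generator, making runs
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .census import TransitionCounts
from .params import HierParams

__all__ = ["PosteriorSample", "sample_posterior"]

_COEF_SD = 1000.0
_SIGMA_UPPER = 10.0
_F_UPPER = 10.0
_TARGET_ACC = 0.44


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """Ordered posterior draws stored as stacked arrays per parameter."""

    draws: dict[str, np.ndarray]
    n_keep: int
    n_burn: int
    seed: int
    acceptance: dict[str, float]
    stream_map: np.ndarray

    def __len__(self) -> int:
        return self.n_keep

    def get_draw(self, idx: int) -> HierParams:
        d = {k: np.array(v[idx]) if np.ndim(v[idx]) else float(v[idx])
             for k, v in self.draws.items()}
        return HierParams(stream_map=self.stream_map.copy(), **d)

    def iter_draws(self):
        for i in range(self.n_keep):
            yield self.get_draw(i)

    def credible_interval(self, name: str, level: float = 0.95):
        arr = self.draws[name]
        alpha = 100.0 * (1.0 - level) / 2.0
        return (np.percentile(arr, alpha, axis=0),
                np.percentile(arr, 100.0 - alpha, axis=0))

    def posterior_mean(self, name: str):
        return self.draws[name].mean(axis=0)

    def split_half_gap(self, name: str) -> float:
        """Max |first-half mean - second-half mean| in MC-SE units."""
        arr = np.asarray(self.draws[name], float).reshape(self.n_keep, -1)
        h = self.n_keep // 2
        a, b = arr[:h], arr[h:2 * h]
        se = np.sqrt(a.var(axis=0, ddof=1) / h + b.var(axis=0, ddof=1) / h)
        gap = np.abs(a.mean(axis=0) - b.mean(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, gap / se, 0.0)
        return float(np.max(z))

    def to_jsonl(self, path) -> None:
        """One JSON object per draw after a metadata header line."""
        with open(path, "w") as fh:
            header = {"_meta": {"n_keep": self.n_keep, "n_burn": self.n_burn,
                                "seed": self.seed,
                                "stream_map": self.stream_map.tolist()}}
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for i in range(self.n_keep):
                row = {k: (np.asarray(v[i]).tolist() if np.ndim(v[i]) else float(v[i]))
                       for k, v in self.draws.items()}
                fh.write(json.dumps(row, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "PosteriorSample":
        with open(path) as fh:
            meta = json.loads(fh.readline())["_meta"]
            rows = [json.loads(line) for line in fh if line.strip()]
        if not rows:
            raise ValueError(f"{path}: no draws")
        draws = {k: np.asarray([row[k] for row in rows]) for k in rows[0]}
        return cls(draws=draws, n_keep=len(rows), n_burn=meta["n_burn"],
                   seed=meta["seed"], acceptance={},
                   stream_map=np.asarray(meta["stream_map"], int))


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _adult_ll(N, const, mask, m, r, s):
    """Multinomial log-lik terms for an adult count block.

    ``N``/``const``/``mask`` have shapes (..., 4)/(...)/(...); ``m``,
    ``r``, ``s`` broadcast to (...).  Empty strata contribute 0.
    """
    P = np.empty(N.shape)
    surv = 1.0 - m
    P[..., 0] = surv * (1.0 - r)
    P[..., 1] = surv * r * (1.0 - s)
    P[..., 2] = surv * r * s
    P[..., 3] = m
    ll = const + xlogy(N, P).sum(axis=-1)
    if ll.ndim:
        ll[~mask] = 0.0
    elif not mask:
        return np.zeros(())
    return ll


class _Gibbs:
    def __init__(self, counts: TransitionCounts, seed: int):
        counts.validate()
        self.counts = counts
        self.K = counts.n_populations
        self.M = counts.n_transition_months
        self.stream = np.asarray(counts.stream_map, int)
        self.rng = np.random.default_rng(seed)

        # --- dense data ---------------------------------------------------
        self.N1 = np.asarray(counts.adult1, float)            # (K, M, 3, 4)
        self.const1 = (gammaln(self.N1.sum(-1) + 1.0)
                       - gammaln(self.N1 + 1.0).sum(-1))      # (K, M, 3)
        self.has1 = self.N1.sum(-1) > 0
        self.Ns = np.asarray(counts.young_s, float)           # (K, 5)
        self.Nj = np.asarray(counts.young_j, float)
        self.const_s = gammaln(self.Ns.sum(-1) + 1) - gammaln(self.Ns + 1).sum(-1)
        self.const_j = gammaln(self.Nj.sum(-1) + 1) - gammaln(self.Nj + 1).sum(-1)

        # gap strata
        self.gaps = []
        for (k, j, g), n in sorted(counts.adult_gaps.items()):
            n = np.asarray(n, float)
            const = float((gammaln(n.sum(-1) + 1) - gammaln(n + 1).sum(-1)).sum())
            self.gaps.append((k, j, g, n, const))
        self.gaps_by_pop: dict[int, list[int]] = {}
        for idx, (k, j, g, _, _) in enumerate(self.gaps):
            self.gaps_by_pop.setdefault(k, []).append(idx)

        # recruits collapsed per population (Poisson means are additive)
        self.rec_s = np.zeros(self.K)
        self.rec_j = np.zeros(self.K)
        self.rec_x = np.zeros(self.K)
        self.rec_const = np.zeros(self.K)
        for k, n_s, n_j, x in counts.recruits:
            if x <= 0 and (n_s > 0 or n_j > 0):
                raise ValueError(
                    f"population {k + 1}: recruits observed with zero "
                    "reproductive-adult exposure; density not finite"
                )
            self.rec_s[k] += n_s
            self.rec_j[k] += n_j
            self.rec_x[k] += x
            self.rec_const[k] += (xlogy(n_s, x) + xlogy(n_j, x)
                                  - gammaln(n_s + 1.0) - gammaln(n_j + 1.0))

        self.params = self._initialize()
        self._init_caches()
        self._build_components()

    # -- initialization ---------------------------------------------------
    def _initialize(self) -> HierParams:
        K, M = self.K, self.M
        clip = lambda p, lo=0.01, hi=0.99: float(np.clip(p, lo, hi))

        pooled = self.N1.sum(axis=(0, 1))  # (3, 4)
        stage_eff = np.zeros(3)
        for i in range(3):
            tot = pooled[i].sum()
            m_hat = pooled[i, 3] / tot if tot > 0 else 0.02
            stage_eff[i] = _logit(clip(m_hat, 1e-3, 0.5))

        r0 = np.full((K, 3), 0.5)
        s0 = np.full((K, 3), 0.5)
        by_pop = self.N1.sum(axis=1)  # (K, 3, 4)
        for k in range(K):
            for i in range(3):
                surv = by_pop[k, i, :3].sum()
                psur = pooled[i, :3].sum()
                if surv > 0:
                    r0[k, i] = clip(by_pop[k, i, 1:3].sum() / surv)
                elif psur > 0:
                    r0[k, i] = clip(pooled[i, 1:3].sum() / psur)
                rep = by_pop[k, i, 1:3].sum()
                prep = pooled[i, 1:3].sum()
                if rep > 0:
                    s0[k, i] = clip(by_pop[k, i, 2] / rep)
                elif prep > 0:
                    s0[k, i] = clip(pooled[i, 2] / prep)

        a0 = np.zeros(K)
        tot_s = self.Ns.sum(axis=1)
        pool_s = self.Ns.sum(axis=0)
        pool_surv_s = (pool_s[:4].sum() / pool_s.sum()) if pool_s.sum() else 0.8
        for k in range(K):
            sy = self.Ns[k, :4].sum() / tot_s[k] if tot_s[k] else pool_surv_s
            a0[k] = _logit(clip(sy))
        pool_j = self.Nj.sum(axis=0)
        sj_pool = (pool_j[:4].sum() / pool_j.sum()) if pool_j.sum() else 0.9
        b0 = float(_logit(clip(sj_pool)) - _logit(clip(pool_surv_s)))

        def chain_init(pool):
            surv = pool[:4].sum()
            adv = pool[1:4].sum()
            g = clip(adv / surv) if surv else 0.5
            t1 = clip(pool[1] / adv) if adv else 0.5
            rest = pool[2] + pool[3]
            t2 = clip(pool[2] / rest) if rest else 0.5
            return g, t1, t2

        g_y, t_sj, t_sn = chain_init(pool_s)
        g_j, t_jn, t_js = chain_init(pool_j)

        f0 = np.full(K, 0.01)
        for k in range(K):
            if self.rec_x[k] > 0:
                f0[k] = float(np.clip((self.rec_s[k] + self.rec_j[k])
                                      / self.rec_x[k], 1e-3, _F_UPPER - 0.1))
        tot_rec = self.rec_s.sum() + self.rec_j.sum()
        phi0 = clip(self.rec_s.sum() / tot_rec) if tot_rec else 0.5

        return HierParams(
            stage_effect=stage_eff,
            pop_effect=np.zeros(K),
            month_effect=np.zeros((2, M)),
            sigma_month=np.array([0.5, 0.5]),
            r=r0, s=s0, a=a0, b=b0,
            g_y=g_y, t_sj=t_sj, t_sn=t_sn, g_j=g_j, t_jn=t_jn, t_js=t_js,
            f=f0, phi=phi0,
            stream_map=self.stream.copy(),
        )

    # -- likelihood pieces -------------------------------------------------
    def _gap_ll_one(self, idx: int) -> float:
        k, j, g, n, const = self.gaps[idx]
        p = self.params
        q = self.stream[k]
        rk, sk = p.r[k], p.s[k]
        # mortality for every month of the span in one shot: (g, 3)
        m = _expit((p.stage_effect + p.pop_effect[k])[None, :]
                   + p.month_effect[q, j:j + g][:, None])
        surv = 1.0 - m
        kern = np.eye(3)
        step = np.empty((3, 3))
        for t in range(g):
            step[0] = surv[t] * (1.0 - rk)
            step[1] = surv[t] * rk * (1.0 - sk)
            step[2] = surv[t] * rk * sk
            kern = step @ kern
        prob = np.empty((3, 4))
        prob[:, :3] = kern.T  # (from, to-live)
        np.clip(1.0 - prob[:, :3].sum(axis=1), 0.0, 1.0, out=prob[:, 3])
        return const + float(xlogy(n, prob).sum())

    def _young_ll(self, k: int) -> tuple[float, float]:
        p = self.params
        sy = _expit(p.a[k])
        sj = _expit(p.a[k] + p.b)
        ps = np.array([sy * (1 - p.g_y), sy * p.g_y * p.t_sj,
                       sy * p.g_y * (1 - p.t_sj) * p.t_sn,
                       sy * p.g_y * (1 - p.t_sj) * (1 - p.t_sn), 1 - sy])
        pj = np.array([sj * (1 - p.g_j), sj * p.g_j * p.t_jn,
                       sj * p.g_j * (1 - p.t_jn) * p.t_js,
                       sj * p.g_j * (1 - p.t_jn) * (1 - p.t_js), 1 - sj])
        ls = self.const_s[k] + float(xlogy(self.Ns[k], ps).sum())
        lj = self.const_j[k] + float(xlogy(self.Nj[k], pj).sum())
        return ls, lj

    def _recruit_ll(self, k: int) -> float:
        if self.rec_x[k] == 0 and self.rec_s[k] == 0 and self.rec_j[k] == 0:
            return 0.0
        p = self.params
        fk = p.f[k]
        return float(xlogy(self.rec_s[k], p.phi * fk)
                     + xlogy(self.rec_j[k], (1.0 - p.phi) * fk)
                     - fk * self.rec_x[k] + self.rec_const[k])

    def _month_prior(self, q: int) -> float:
        p = self.params
        sd = p.sigma_month[q]
        e = p.month_effect[q]
        return float(-0.5 * np.sum((e / sd) ** 2)
                     - e.size * np.log(sd * np.sqrt(2 * np.pi)))

    def _init_caches(self) -> None:
        p = self.params
        # T1[k, j, i]: per-stratum adult log-lik terms
        self.T1 = np.zeros((self.K, self.M, 3))
        for k in range(self.K):
            q = self.stream[k]
            m = _expit(p.stage_effect[None, :] + p.month_effect[q][:, None]
                       + p.pop_effect[k])
            self.T1[k] = _adult_ll(self.N1[k], self.const1[k], self.has1[k],
                                   m, p.r[k][None, :], p.s[k][None, :])
        self.gap_cache = np.array([self._gap_ll_one(i) for i in range(len(self.gaps))])
        pairs = [self._young_ll(k) for k in range(self.K)]
        self.Ys = np.array([x[0] for x in pairs])
        self.Yj = np.array([x[1] for x in pairs])
        self.R = np.array([self._recruit_ll(k) for k in range(self.K)])
        self.mp = np.array([self._month_prior(0), self._month_prior(1)])
        total = (self.T1.sum() + self.gap_cache.sum() + self.Ys.sum()
                 + self.Yj.sum() + self.R.sum())
        if not np.isfinite(total):
            bad = []
            if not np.isfinite(self.T1.sum() + self.gap_cache.sum()):
                bad.append("adult")
            if not np.isfinite(self.Ys.sum() + self.Yj.sum()):
                bad.append("young")
            if not np.isfinite(self.R.sum()):
                bad.append("recruit")
            raise RuntimeError(
                "posterior density not finite at initialization "
                f"({'/'.join(bad)} strata)"
            )

    # -- component bookkeeping ----------------------------------------------
    def _build_components(self) -> None:
        stream_pops = [np.flatnonzero(self.stream == q) for q in range(2)]
        all_gaps = list(range(len(self.gaps)))
        comps = []

        def block(kind, idx, N, const, mask, gaps):
            comps.append({
                "kind": kind, "idx": idx,
                "N": np.ascontiguousarray(N), "const": np.ascontiguousarray(const),
                "mask": np.ascontiguousarray(mask), "gaps": gaps,
            })

        for i in range(3):
            block("stage_effect", i, self.N1[:, :, i, :], self.const1[:, :, i],
                  self.has1[:, :, i], all_gaps)
        for k in range(1, self.K):
            block("pop_effect", k, self.N1[k], self.const1[k], self.has1[k],
                  self.gaps_by_pop.get(k, []))
        for q in range(2):
            ks = stream_pops[q]
            for j in range(self.M):
                gaps = [gi for gi, (k, j0, g, _, _) in enumerate(self.gaps)
                        if self.stream[k] == q and j0 <= j < j0 + g]
                block("month_effect", (q, j, ks), self.N1[ks, j],
                      self.const1[ks, j], self.has1[ks, j], gaps)
            comps.append({"kind": "sigma_month", "idx": q})
        for k in range(self.K):
            for i in range(3):
                gaps = self.gaps_by_pop.get(k, [])
                block("r", (k, i), self.N1[k, :, i, :], self.const1[k, :, i],
                      self.has1[k, :, i], gaps)
                block("s", (k, i), self.N1[k, :, i, :], self.const1[k, :, i],
                      self.has1[k, :, i], gaps)
        for k in range(self.K):
            comps.append({"kind": "a", "idx": k})
        comps.append({"kind": "b", "idx": None})
        for name in ("g_y", "t_sj", "t_sn", "g_j", "t_jn", "t_js"):
            comps.append({"kind": name, "idx": None})
        for k in range(self.K):
            comps.append({"kind": "f", "idx": k})
        comps.append({"kind": "phi", "idx": None})

        for c in comps:
            c["scale"] = 0.3
            c["acc"] = 0
            c["tries"] = 0
            c["bacc"] = 0
            c["bn"] = 0
        self.components = comps

    # -- adult block evaluation ---------------------------------------------
    def _adult_block_ll(self, comp) -> np.ndarray:
        """Recompute the T1 terms for one adult-parameter component."""
        p = self.params
        kind, idx = comp["kind"], comp["idx"]
        if kind == "stage_effect":
            i = idx
            m = _expit(p.stage_effect[i] + p.month_effect[self.stream][:, :]
                       + p.pop_effect[:, None])  # (K, M)
            return _adult_ll(comp["N"], comp["const"], comp["mask"],
                             m, p.r[:, i][:, None], p.s[:, i][:, None])
        if kind == "pop_effect":
            k = idx
            m = _expit(p.stage_effect[None, :]
                       + p.month_effect[self.stream[k]][:, None]
                       + p.pop_effect[k])  # (M, 3)
            return _adult_ll(comp["N"], comp["const"], comp["mask"],
                             m, p.r[k][None, :], p.s[k][None, :])
        if kind == "month_effect":
            q, j, ks = idx
            m = _expit(p.stage_effect[None, :] + p.month_effect[q, j]
                       + p.pop_effect[ks][:, None])  # (nk, 3)
            return _adult_ll(comp["N"], comp["const"], comp["mask"],
                             m, p.r[ks], p.s[ks])
        # r or s component: (k, i) over all months
        k, i = idx
        m = _expit(p.stage_effect[i] + p.month_effect[self.stream[k]]
                   + p.pop_effect[k])  # (M,)
        return _adult_ll(comp["N"], comp["const"], comp["mask"],
                         m, p.r[k, i], p.s[k, i])

    def _write_T1(self, comp, ll) -> None:
        kind, idx = comp["kind"], comp["idx"]
        if kind == "stage_effect":
            self.T1[:, :, idx] = ll
        elif kind == "pop_effect":
            self.T1[idx] = ll
        elif kind == "month_effect":
            q, j, ks = idx
            self.T1[ks, j] = ll
        else:
            k, i = idx
            self.T1[k, :, i] = ll

    def _read_T1_sum(self, comp) -> float:
        kind, idx = comp["kind"], comp["idx"]
        if kind == "stage_effect":
            return float(self.T1[:, :, idx].sum())
        if kind == "pop_effect":
            return float(self.T1[idx].sum())
        if kind == "month_effect":
            q, j, ks = idx
            return float(self.T1[ks, j].sum())
        k, i = idx
        return float(self.T1[k, :, i].sum())

    # -- generic component update ------------------------------------------
    def _update(self, comp, adapt: bool) -> None:
        kind, idx = comp["kind"], comp["idx"]
        p = self.params
        step = comp["scale"] * self.rng.normal()
        logu = np.log(self.rng.random())
        delta = 0.0
        accepted = False

        if kind in ("stage_effect", "pop_effect", "month_effect", "r", "s"):
            # adult-likelihood components
            if kind == "stage_effect":
                tgt, ti = p.stage_effect, idx
                old = tgt[ti]
                new = old + step
                delta += (old * old - new * new) / (2.0 * _COEF_SD ** 2)
            elif kind == "pop_effect":
                tgt, ti = p.pop_effect, idx
                old = tgt[ti]
                new = old + step
                delta += (old * old - new * new) / (2.0 * _COEF_SD ** 2)
            elif kind == "month_effect":
                q, j, _ = idx
                tgt, ti = p.month_effect, (q, j)
                old = tgt[ti]
                new = old + step
                sd = p.sigma_month[q]
                delta += (old * old - new * new) / (2.0 * sd * sd)
            else:
                tgt, ti = getattr(p, kind), idx
                old = tgt[ti]
                new = float(_expit(_logit(old) + step))
                delta += np.log(new * (1 - new)) - np.log(old * (1 - old))
            old_sum = self._read_T1_sum(comp)
            tgt[ti] = new
            ll = self._adult_block_ll(comp)
            delta += float(ll.sum()) - old_sum
            gap_idx = comp["gaps"]
            new_gaps = [self._gap_ll_one(gi) for gi in gap_idx]
            if gap_idx:
                delta += sum(new_gaps) - float(sum(self.gap_cache[gi] for gi in gap_idx))
            if logu < delta:
                self._write_T1(comp, ll)
                for gi, v in zip(gap_idx, new_gaps):
                    self.gap_cache[gi] = v
                if kind == "month_effect":
                    self.mp[idx[0]] = self._month_prior(idx[0])
                accepted = True
            else:
                tgt[ti] = old

        elif kind == "sigma_month":
            q = idx
            old = p.sigma_month[q]
            z = _logit(old / _SIGMA_UPPER) + step
            new = _SIGMA_UPPER * _expit(z)
            delta += (np.log(new * (_SIGMA_UPPER - new))
                      - np.log(old * (_SIGMA_UPPER - old)))
            p.sigma_month[q] = new
            new_mp = self._month_prior(q)
            delta += new_mp - self.mp[q]
            if logu < delta:
                self.mp[q] = new_mp
                accepted = True
            else:
                p.sigma_month[q] = old

        elif kind == "a":
            k = idx
            old = p.a[k]
            new = old + step
            delta += (old * old - new * new) / (2.0 * _COEF_SD ** 2)
            p.a[k] = new
            ls, lj = self._young_ll(k)
            delta += (ls - self.Ys[k]) + (lj - self.Yj[k])
            if logu < delta:
                self.Ys[k], self.Yj[k] = ls, lj
                accepted = True
            else:
                p.a[k] = old

        elif kind == "b":
            old = p.b
            new = old + step
            delta += (old * old - new * new) / (2.0 * _COEF_SD ** 2)
            p.b = new
            pairs = [self._young_ll(k) for k in range(self.K)]
            new_j = np.array([x[1] for x in pairs])
            delta += float(new_j.sum() - self.Yj.sum())
            if logu < delta:
                self.Yj = new_j
                accepted = True
            else:
                p.b = old

        elif kind in ("g_y", "t_sj", "t_sn", "g_j", "t_jn", "t_js"):
            old = getattr(p, kind)
            new = float(_expit(_logit(old) + step))
            delta += np.log(new * (1 - new)) - np.log(old * (1 - old))
            setattr(p, kind, new)
            pairs = [self._young_ll(k) for k in range(self.K)]
            new_s = np.array([x[0] for x in pairs])
            new_j = np.array([x[1] for x in pairs])
            delta += float(new_s.sum() + new_j.sum() - self.Ys.sum() - self.Yj.sum())
            if logu < delta:
                self.Ys, self.Yj = new_s, new_j
                accepted = True
            else:
                setattr(p, kind, old)

        elif kind == "f":
            k = idx
            old = p.f[k]
            z = _logit(old / _F_UPPER) + step
            new = _F_UPPER * _expit(z)
            delta += (np.log(new * (_F_UPPER - new))
                      - np.log(old * (_F_UPPER - old)))
            p.f[k] = new
            new_r = self._recruit_ll(k)
            delta += new_r - self.R[k]
            if logu < delta:
                self.R[k] = new_r
                accepted = True
            else:
                p.f[k] = old

        elif kind == "phi":
            old = p.phi
            new = float(_expit(_logit(old) + step))
            delta += np.log(new * (1 - new)) - np.log(old * (1 - old))
            p.phi = new
            new_r = np.array([self._recruit_ll(k) for k in range(self.K)])
            delta += float(new_r.sum() - self.R.sum())
            if logu < delta:
                self.R = new_r
                accepted = True
            else:
                p.phi = old
        else:  # pragma: no cover
            raise AssertionError(kind)

        comp["tries"] += 1
        comp["acc"] += accepted
        if adapt:
            comp["bn"] += 1
            comp["bacc"] += accepted
            if comp["bn"] == 25:
                rate = comp["bacc"] / 25.0
                comp["scale"] = float(np.clip(
                    comp["scale"] * np.exp(0.6 * (rate - _TARGET_ACC)),
                    1e-3, 10.0,
                ))
                comp["bn"] = 0
                comp["bacc"] = 0

    # -- main loop ----------------------------------------------------------
    def run(self, n_keep: int, n_burn: int) -> dict[str, np.ndarray]:
        store: dict[str, list] = {
            "stage_effect": [], "pop_effect": [], "month_effect": [],
            "sigma_month": [], "r": [], "s": [], "a": [], "b": [],
            "g_y": [], "t_sj": [], "t_sn": [], "g_j": [], "t_jn": [],
            "t_js": [], "f": [], "phi": [],
        }
        for sweep in range(n_burn + n_keep):
            adapt = sweep < n_burn
            for comp in self.components:
                self._update(comp, adapt)
            if sweep >= n_burn:
                p = self.params
                for name in store:
                    v = getattr(p, name)
                    store[name].append(v.copy() if isinstance(v, np.ndarray) else v)
        return {k: np.asarray(v) for k, v in store.items()}


def sample_posterior(counts: TransitionCounts, n_keep: int = 10000,
                     n_burn: int = 5000, seed: int = 0) -> PosteriorSample:
    """Draw from the posterior over :class:`HierParams` given counts.

    Defaults follow the study protocol: 10000 retained draws after a
    burn-in of 5000.  Identical seeds give bit-identical draw sequences.
    """
    if n_keep < 0 or n_burn < 0:
        raise ValueError("n_keep and n_burn must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        gibbs = _Gibbs(counts, seed)
        draws = gibbs.run(n_keep, n_burn)
    acceptance = {}
    for c in gibbs.components:
        key = c["kind"] if c["idx"] is None else f"{c['kind']}[{c['idx']}]"
        if c["kind"] == "month_effect":
            q, j, _ = c["idx"]
            key = f"month_effect[{q},{j}]"
        acceptance[key] = c["acc"] / c["tries"] if c["tries"] else 0.0
    return PosteriorSample(
        draws=draws, n_keep=n_keep, n_burn=n_burn, seed=seed,
        acceptance=acceptance, stream_map=gibbs.stream.copy(),
    )
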