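"""Boruta all-relevant feature selection against shuffled shadow features.

Every iteration appends one row-permuted "shadow" copy of every input
feature, fits a forest on the extended matrix, and converts each feature's
mean decrease accuracy (MDA, the mean out-of-bag accuracy loss under
permutation) into a Z score by dividing by the standard deviation of the
per-tree losses.  A feature scores a *hit* when its Z exceeds the maximum Z
among the shadows (MZSA).  Cumulative hit counts are tested against a
Binomial(n_iterations, 1/2) null, two-sided at level ``alpha`` with a
Bonferroni adjustment over all input features: significantly many hits
confirms the feature, significantly few rejects it.  Rejected features stop
competing (they and all shadows leave the matrix before the next
iteration), but shadows are always rebuilt from the *full* input feature
set, so MZSA remains the best chance importance among all p features — a
shadow pool that shrank with the survivors would lower the bar exactly for
the late, hardest decisions and let chance-correlated features through.
Iteration stops when nothing is tentative or after ``max_iter`` rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import ensemble_classifier as ens
from .labeling import LabelVector

logger = logging.getLogger("autoborutarf")

SHADOW_PREFIX = "shadow__"


@dataclass
class IterationRecord:
    iteration: int
    z_scores: pd.Series  # over surviving originals and that round's shadows
    mzsa: float
    confirmed: list[str]
    rejected: list[str]


@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    history: list[IterationRecord]
    iterations_run: int
    hits: pd.Series | None = None  # cumulative hits per feature
    trials: pd.Series | None = None  # iterations each feature was present

    def __post_init__(self) -> None:
        groups = [set(self.confirmed), set(self.rejected), set(self.tentative)]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            raise ValueError("confirmed/rejected/tentative must be disjoint")

    @property
    def all_features(self) -> set[str]:
        return set(self.confirmed) | set(self.rejected) | set(self.tentative)

    def history_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.history:
            for feat, z in rec.z_scores.items():
                rows.append({"iteration": rec.iteration, "feature": feat,
                             "z": z, "mzsa": rec.mzsa})
        return pd.DataFrame(rows)


def make_shadow(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append one independently row-permuted copy of every column."""
    shadows = {}
    for col in X.columns:
        perm = rng.permutation(len(X))
        shadows[SHADOW_PREFIX + str(col)] = X[col].to_numpy()[perm]
    sh = pd.DataFrame(shadows, index=X.index)
    return pd.concat([X, sh], axis=1)


def importance_zscores(X_ext: pd.DataFrame, y, rng: np.random.Generator,
                       n_trees: int = 500, bootstrap_fraction: float = 0.632,
                       bootstrap_replace: bool = False) -> pd.Series:
    """Z = MDA / sd(per-tree OOB accuracy losses), per column of ``X_ext``.

    A feature whose per-tree losses have zero spread (e.g. one no tree ever
    splits on) gets Z = 0 by convention.
    """
    if isinstance(y, LabelVector):
        y = y.y
    ya = np.asarray(y).astype(np.int64)
    if len(np.unique(ya)) < 2:
        raise ens.SingleClassError("both classes required")
    model = ens.train_forest(X_ext, ya, n_trees=n_trees, seed=rng,
                             bootstrap_fraction=bootstrap_fraction,
                             bootstrap_replace=bootstrap_replace)
    losses = ens.oob_permutation_losses(model, X_ext, ya,
                                        seed=int(rng.integers(2**31)))
    mda = losses.mean(axis=0)
    sd = losses.std(axis=0, ddof=1)
    z = np.where(sd > 0, mda / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z, index=X_ext.columns, name="z")


def boruta_run(X: pd.DataFrame, y, rng: np.random.Generator | int = 0,
               max_iter: int = 200, alpha: float = 0.01, n_trees: int = 500,
               bootstrap_fraction: float = 0.632,
               bootstrap_replace: bool = False,
               min_shadows: int = 5) -> BorutaResult:
    """Iterate shadows/Z/MZSA until every feature is decided or ``max_iter``.

    The shadow pool always spans the full input feature set, so for tiny
    inputs ``min_shadows`` extra shuffled copies keep MZSA a meaningful
    maximum (the guard the algorithm's reference implementation also uses).
    """
    if isinstance(y, LabelVector):
        y = y.y
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = rng if isinstance(rng, np.random.Generator) else \
        np.random.default_rng(rng)

    features = [str(c) for c in X.columns]
    X = X.copy()
    X.columns = features
    hits = pd.Series(0, index=features, dtype=int)
    trials = pd.Series(0, index=features, dtype=int)
    confirmed: list[str] = []
    rejected: list[str] = []
    tentative = list(features)
    history: list[IterationRecord] = []

    it = 0
    while tentative and it < max_iter:
        it += 1
        active = [f for f in features if f not in set(rejected)]
        X_act = X[active]
        # shadows are drawn from every input feature (not only survivors)
        sh = {SHADOW_PREFIX + f: X[f].to_numpy()[rng.permutation(len(X))]
              for f in features}
        for i in range(min_shadows - len(features)):
            src = features[i % len(features)]
            sh[f"{SHADOW_PREFIX}pad{i}__{src}"] = \
                X[src].to_numpy()[rng.permutation(len(X))]
        X_ext = pd.concat([X_act, pd.DataFrame(sh, index=X.index)], axis=1)
        z = importance_zscores(X_ext, y, rng, n_trees=n_trees,
                               bootstrap_fraction=bootstrap_fraction,
                               bootstrap_replace=bootstrap_replace)
        shadow_z = z[[c for c in z.index if c.startswith(SHADOW_PREFIX)]]
        mzsa = float(shadow_z.max())
        orig_z = z[active]
        hit_now = orig_z[orig_z > mzsa].index
        hits[hit_now] += 1
        trials[active] += 1

        new_confirmed, new_rejected = [], []
        # Bonferroni over all input features, as in the original algorithm's
        # default multiple-testing adjustment
        level = alpha / 2 / len(features)
        for f in list(tentative):
            n_tr, h = int(trials[f]), int(hits[f])
            # two-sided binomial test at level alpha, p0 = 1/2
            p_hi = float(binom.sf(h - 1, n_tr, 0.5))
            p_lo = float(binom.cdf(h, n_tr, 0.5))
            if p_hi < level:
                new_confirmed.append(f)
            elif p_lo < level:
                new_rejected.append(f)
        for f in new_confirmed:
            tentative.remove(f)
            confirmed.append(f)
        for f in new_rejected:
            tentative.remove(f)
            rejected.append(f)
        history.append(IterationRecord(iteration=it, z_scores=z, mzsa=mzsa,
                                       confirmed=new_confirmed,
                                       rejected=new_rejected))

    if not confirmed and not tentative:
        logger.info("Boruta: empty selection (all %d features rejected)",
                    len(rejected))
    return BorutaResult(confirmed=confirmed, rejected=rejected,
                        tentative=tentative, history=history,
                        iterations_run=it, hits=hits, trials=trials)
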