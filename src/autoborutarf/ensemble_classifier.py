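"""Random forest of CARTs with out-of-bag bookkeeping, plus EasyEnsemble.

Each of the (default 1,000) CARTs is fit on an independent draw of
``ceil(0.632 * N)`` cell lines.  The 0.632 is the classic expected unique
fraction of a bootstrap, so the default draw is *without* replacement;
with-replacement draws are available via ``bootstrap_replace``.  Predictions
are hard votes over trees, with the sensitive-vote fraction kept as the
continuous score; an exact tie predicts non-sensitive.

For drugs whose imbalance ratio IR = |non-sensitive| / |sensitive| exceeds 2,
EasyEnsemble partitions the majority class into T = floor(IR) disjoint
subsets, trains one forest per balanced subset (subset plus all minority
samples) and takes the majority vote of the T forests.

Trees live in flattened per-node arrays (split feature, threshold, child
pointers, leaf class).  Building, voting and out-of-bag permutation
importance are numba kernels over that encoding — the Boruta stage refits a
forest and rescores every feature hundreds of times, which rules out
per-tree Python overhead.  The flat arrays double as the serialisation
format (:meth:`ForestModel.to_frame`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .labeling import LabelVector

logger = logging.getLogger("autoborutarf")


class SingleClassError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_forest(X, y, n_trees, m, mtry, replace, seed):
    """Grow ``n_trees`` Gini CARTs to purity on random m-subsamples.

    Returns flattened node arrays (child ids are tree-local), tree offsets
    and the in-bag indicator.  Leaf class is 1 only on a strict majority of
    class-1 samples, matching the non-sensitive tie rule at the vote stage.
    """
    np.random.seed(seed)
    n, p = X.shape
    cap = n_trees * 2 * m
    feat = np.full(cap, -1, np.int64)
    thr = np.zeros(cap, np.float64)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    leafcls = np.zeros(cap, np.int64)
    tree_ptr = np.zeros(n_trees + 1, np.int64)
    inbag = np.zeros((n_trees, n), np.bool_)

    pool = np.empty(n, np.int64)  # sampling pool for without-replacement
    smp = np.empty(m, np.int64)  # per-tree sample indices, partitioned in place
    stack_node = np.empty(2 * m + 1, np.int64)
    stack_lo = np.empty(2 * m + 1, np.int64)
    stack_hi = np.empty(2 * m + 1, np.int64)
    fperm = np.empty(p, np.int64)
    vbuf = np.empty(m, np.float64)
    cbuf = np.empty(m, np.int64)
    pos = 0

    for t in range(n_trees):
        tree_ptr[t] = pos
        if replace:
            for i in range(m):
                smp[i] = np.random.randint(0, n)
        else:
            for i in range(n):
                pool[i] = i
            for i in range(m):
                j = i + np.random.randint(0, n - i)
                tmp = pool[i]
                pool[i] = pool[j]
                pool[j] = tmp
                smp[i] = pool[i]
        for i in range(m):
            inbag[t, smp[i]] = True

        n_nodes = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = m
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            k = hi - lo
            c1 = 0
            for i in range(lo, hi):
                c1 += y[smp[i]]
            # pure or unsplittable -> leaf
            if c1 == 0 or c1 == k or k < 2:
                leafcls[pos + node] = 1 if 2 * c1 > k else 0
                continue

            # draw features without replacement until mtry non-constant
            # candidates were scored (or the pool is exhausted)
            for i in range(p):
                fperm[i] = i
            best_gini = 1e18
            best_f = -1
            best_thr = 0.0
            tried = 0
            drawn = 0
            while drawn < p and tried < mtry:
                j = drawn + np.random.randint(0, p - drawn)
                tmp = fperm[drawn]
                fperm[drawn] = fperm[j]
                fperm[j] = tmp
                f = fperm[drawn]
                drawn += 1
                for i in range(k):
                    vbuf[i] = X[smp[lo + i], f]
                order = np.argsort(vbuf[:k], kind="mergesort")
                if vbuf[order[0]] == vbuf[order[k - 1]]:
                    continue  # constant in this node
                tried += 1
                c1L = 0
                for i in range(k - 1):
                    c1L += y[smp[lo + order[i]]]
                    if vbuf[order[i]] == vbuf[order[i + 1]]:
                        continue
                    nL = i + 1
                    nR = k - nL
                    c1R = c1 - c1L
                    giniL = 1.0 - ((c1L / nL) ** 2 + ((nL - c1L) / nL) ** 2)
                    giniR = 1.0 - ((c1R / nR) ** 2 + ((nR - c1R) / nR) ** 2)
                    g = (nL * giniL + nR * giniR) / k
                    if g < best_gini - 1e-12:
                        best_gini = g
                        best_f = f
                        best_thr = 0.5 * (vbuf[order[i]] + vbuf[order[i + 1]])
            if best_f < 0:
                # every candidate constant: majority leaf
                leafcls[pos + node] = 1 if 2 * c1 > k else 0
                continue

            # partition smp[lo:hi] by the chosen split
            i = lo
            j = hi - 1
            while i <= j:
                if X[smp[i], best_f] <= best_thr:
                    i += 1
                else:
                    tmp = smp[i]
                    smp[i] = smp[j]
                    smp[j] = tmp
                    j -= 1
            mid = i
            if mid == lo or mid == hi:
                # numerically unsplittable despite distinct values
                leafcls[pos + node] = 1 if 2 * c1 > k else 0
                continue
            feat[pos + node] = best_f
            thr[pos + node] = best_thr
            left[pos + node] = n_nodes
            right[pos + node] = n_nodes + 1
            stack_node[sp] = n_nodes
            stack_lo[sp] = lo
            stack_hi[sp] = mid
            stack_node[sp + 1] = n_nodes + 1
            stack_lo[sp + 1] = mid
            stack_hi[sp + 1] = hi
            sp += 2
            n_nodes += 2
        pos += n_nodes
    tree_ptr[n_trees] = pos
    return (feat[:pos].copy(), thr[:pos].copy(), left[:pos].copy(),
            right[:pos].copy(), leafcls[:pos].copy(), tree_ptr, inbag)


@njit(cache=True)
def _vote_counts(feat, thr, left, right, leafcls, tree_ptr, X):
    """Number of trees voting class 1, per row of X."""
    n = X.shape[0]
    n_trees = tree_ptr.shape[0] - 1
    votes = np.zeros(n, np.int64)
    for t in range(n_trees):
        base = tree_ptr[t]
        for i in range(n):
            node = base
            while left[node] != -1:
                if X[i, feat[node]] <= thr[node]:
                    node = base + left[node]
                else:
                    node = base + right[node]
            votes[i] += leafcls[node]
    return votes


@njit(cache=True)
def _oob_perm_losses(feat, thr, left, right, leafcls, tree_ptr, inbag, X, y,
                     seed):
    """Per-tree out-of-bag accuracy loss for permuting each feature.

    Features a tree never splits on contribute an exact 0 for that tree.
    """
    np.random.seed(seed)
    n_trees = tree_ptr.shape[0] - 1
    n, p = X.shape
    losses = np.zeros((n_trees, p))
    for t in range(n_trees):
        base = tree_ptr[t]
        end = tree_ptr[t + 1]
        n_oob = 0
        for i in range(n):
            if not inbag[t, i]:
                n_oob += 1
        if n_oob == 0:
            continue
        oob = np.empty(n_oob, np.int64)
        j = 0
        for i in range(n):
            if not inbag[t, i]:
                oob[j] = i
                j += 1
        Xo = X[oob]
        acc0 = 0.0
        for i in range(n_oob):
            node = base
            while left[node] != -1:
                if Xo[i, feat[node]] <= thr[node]:
                    node = base + left[node]
                else:
                    node = base + right[node]
            if leafcls[node] == y[oob[i]]:
                acc0 += 1.0
        acc0 /= n_oob
        used = np.zeros(p, np.bool_)
        for k in range(base, end):
            if left[k] != -1:
                used[feat[k]] = True
        col = np.empty(n_oob)
        for f in range(p):
            if not used[f]:
                continue
            perm = np.random.permutation(n_oob)
            for i in range(n_oob):
                col[i] = Xo[i, f]
            for i in range(n_oob):
                Xo[i, f] = col[perm[i]]
            acc = 0.0
            for i in range(n_oob):
                node = base
                while left[node] != -1:
                    if Xo[i, feat[node]] <= thr[node]:
                        node = base + left[node]
                    else:
                        node = base + right[node]
                if leafcls[node] == y[oob[i]]:
                    acc += 1.0
            acc /= n_oob
            for i in range(n_oob):
                Xo[i, f] = col[i]
            losses[t, f] = acc0 - acc
    return losses


# ---------------------------------------------------------------------------
# forest model
# ---------------------------------------------------------------------------


@dataclass
class ForestModel:
    """A voting forest in flattened per-node array form."""

    feature_names: list[str]
    node_feature: np.ndarray
    node_threshold: np.ndarray
    node_left: np.ndarray  # -1 marks a leaf; child ids are tree-local
    node_right: np.ndarray
    leaf_class: np.ndarray
    tree_ptr: np.ndarray  # (n_trees + 1,) node offsets
    bootstrap_size: int
    inbag: np.ndarray | None = None  # (n_trees, n_train) bool
    seed: int | None = None

    @property
    def n_trees(self) -> int:
        return len(self.tree_ptr) - 1

    def oob_sample_ids(self, t: int) -> np.ndarray:
        if self.inbag is None:
            raise ValueError("training bag information not retained")
        return np.where(~self.inbag[t])[0]

    def _check_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(map(str, X.columns)) != list(map(str, self.feature_names)):
                raise SchemaError("feature columns do not match training")
            X = X.to_numpy()
        X = np.ascontiguousarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return X

    def predict(self, X):
        """(labels, sensitive-vote fractions); vote ties -> non-sensitive."""
        X = self._check_X(X)
        votes = _vote_counts(self.node_feature, self.node_threshold,
                             self.node_left, self.node_right, self.leaf_class,
                             self.tree_ptr, X)
        frac = votes / self.n_trees
        return frac > 0.5, frac

    def to_frame(self) -> pd.DataFrame:
        """Portable tabular encoding: one row per node."""
        tree_id = np.repeat(np.arange(self.n_trees), np.diff(self.tree_ptr))
        node_id = np.concatenate(
            [np.arange(self.tree_ptr[t + 1] - self.tree_ptr[t])
             for t in range(self.n_trees)])
        return pd.DataFrame({
            "tree": tree_id, "node": node_id,
            "feature": self.node_feature, "threshold": self.node_threshold,
            "left": self.node_left, "right": self.node_right,
            "leaf_class": self.leaf_class,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_names,
                   bootstrap_size: int) -> "ForestModel":
        df = df.sort_values(["tree", "node"], kind="stable")
        counts = df.groupby("tree", sort=True).size().to_numpy()
        tree_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return cls(feature_names=list(feature_names),
                   node_feature=df["feature"].to_numpy(np.int64),
                   node_threshold=df["threshold"].to_numpy(float),
                   node_left=df["left"].to_numpy(np.int64),
                   node_right=df["right"].to_numpy(np.int64),
                   leaf_class=df["leaf_class"].to_numpy(np.int64),
                   tree_ptr=tree_ptr, bootstrap_size=bootstrap_size)


def train_forest(X, y, n_trees: int = 1000, seed: int | np.random.Generator = 0,
                 bootstrap_fraction: float = 0.632,
                 bootstrap_replace: bool = False) -> ForestModel:
    """Fit ``n_trees`` CARTs, each on a seeded draw of ceil(0.632 N) samples.

    Gini splits, mtry = ceil(sqrt(p)), grown to purity (min leaf 1).
    ``y`` is a boolean vector (True = sensitive) or a LabelVector.
    """
    if isinstance(y, LabelVector):
        y = y.y
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        str(i) for i in range(np.asarray(X).shape[1])]
    Xa = (X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X))
    Xa = np.ascontiguousarray(Xa, dtype=float)
    ya = np.asarray(y).astype(np.int64)
    n, p = Xa.shape
    if len(np.unique(ya)) < 2:
        raise SingleClassError("training labels contain a single class")
    if min(np.bincount(ya)) < 2:
        raise SingleClassError("need at least 2 samples per class")

    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    m = int(np.ceil(bootstrap_fraction * n))
    mtry = int(np.ceil(np.sqrt(p)))
    kernel_seed = int(rng.integers(2**31))
    feat, thr, left, right, leafcls, tree_ptr, inbag = _build_forest(
        Xa, ya, n_trees, m, mtry, bootstrap_replace, kernel_seed)
    return ForestModel(feature_names=names, node_feature=feat,
                       node_threshold=thr, node_left=left, node_right=right,
                       leaf_class=leafcls, tree_ptr=tree_ptr,
                       bootstrap_size=m, inbag=inbag,
                       seed=None if isinstance(seed, np.random.Generator)
                       else int(seed))


def oob_permutation_losses(model: ForestModel, X, y,
                           seed: int = 0) -> np.ndarray:
    """(n_trees, p) matrix of per-tree OOB accuracy losses per feature."""
    Xa = model._check_X(X)
    ya = np.asarray(y).astype(np.int64)
    if model.inbag is None:
        raise ValueError("model was not trained here (no bag information)")
    return _oob_perm_losses(model.node_feature, model.node_threshold,
                            model.node_left, model.node_right,
                            model.leaf_class, model.tree_ptr, model.inbag,
                            Xa, ya, seed)


def predict_vote(model: ForestModel, X):
    """Voting prediction; returns (labels, sensitive-vote fraction)."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# EasyEnsemble
# ---------------------------------------------------------------------------


@dataclass
class EasyEnsembleModel:
    """T forests, one per balanced majority-subset, combined by majority vote."""

    forests: list[ForestModel]
    majority_subsets: list[np.ndarray]  # index partitions of the majority class
    minority_idx: np.ndarray

    @property
    def T(self) -> int:
        return len(self.forests)

    def predict(self, X):
        n = len(X) if isinstance(X, pd.DataFrame) else np.asarray(X).shape[0]
        labels = np.zeros(n, dtype=np.int64)
        scores = np.zeros(n, dtype=float)
        for f in self.forests:
            lab, frac = f.predict(X)
            labels += lab.astype(np.int64)
            scores += frac
        # majority of sub-forest votes; exact tie -> non-sensitive
        return labels * 2 > self.T, scores / self.T


def partition_majority(n_majority: int, T: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Random disjoint split of 0..n_majority-1 into T near-equal subsets.

    The remainder r = n mod T is spread over the first r subsets, so sizes
    differ by at most one.
    """
    perm = rng.permutation(n_majority)
    return [np.sort(part) for part in np.array_split(perm, T)]


def train_easy_ensemble(X, y, n_trees: int = 1000,
                        ir_threshold: float = 2.0,
                        seed: int | np.random.Generator = 0,
                        bootstrap_fraction: float = 0.632,
                        bootstrap_replace: bool = False):
    """EasyEnsemble when IR > 2, plain forest otherwise.

    Majority class N (non-sensitive, y False) is split into T = floor(IR)
    disjoint subsets; forest i trains on subset i plus every minority sample.
    Returns an EasyEnsembleModel or, on the bypass path, a ForestModel.
    """
    if isinstance(y, LabelVector):
        y = y.y
    ya = np.asarray(y).astype(bool)
    n_min = int(ya.sum())
    n_maj = int((~ya).sum())
    if n_min == 0 or n_maj == 0:
        raise SingleClassError("both classes required")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    ir = n_maj / n_min
    if ir <= ir_threshold:
        return train_forest(X, ya, n_trees=n_trees, seed=rng,
                            bootstrap_fraction=bootstrap_fraction,
                            bootstrap_replace=bootstrap_replace)
    T = int(np.floor(ir))
    maj_idx = np.where(~ya)[0]
    min_idx = np.where(ya)[0]
    local_parts = partition_majority(n_maj, T, rng)
    subsets = [maj_idx[p] for p in local_parts]
    forests = []
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    for sub in subsets:
        rows = np.concatenate([sub, min_idx])
        if min(len(sub), n_min) < 2:
            raise SingleClassError("degenerate EasyEnsemble subset")
        forests.append(train_forest(Xdf.iloc[rows], ya[rows], n_trees=n_trees,
                                    seed=rng,
                                    bootstrap_fraction=bootstrap_fraction,
                                    bootstrap_replace=bootstrap_replace))
    logger.info("EasyEnsemble: IR=%.3f T=%d subset sizes=%s", ir, T,
                [len(s) for s in subsets])
    return EasyEnsembleModel(forests=forests, majority_subsets=subsets,
                             minority_idx=min_idx)
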