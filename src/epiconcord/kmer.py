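"""Gapped k-mer sequence featurization, linear model training/scoring,
auROC, and expression-class top-decile enrichment.

A gapped k-mer feature is a choice of k informative positions within a
length-l window plus the bases at those positions; every window contributes
one count to C(l, k) features. The trained model scores a sequence as the dot
product of its feature counts with the learned weights.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "KmerParams",
    "KmerModel",
    "ExpressionClass",
    "GappedKmerFeaturizer",
    "featurize",
    "train",
    "score",
    "auroc",
    "top_decile_enrichment",
    "feature_to_pattern",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


@dataclass
class KmerParams:
    l: int = 10
    k: int = 6
    d: int = 3  # accepted for config fidelity; unused by the linear scorer
    revcomp_collapse: bool = True
    top_frac: float = 0.10

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.l:
            raise ValueError("require 1 <= k <= l")
        if not 0 <= self.d <= self.l - self.k:
            raise ValueError("require 0 <= d <= l - k")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionClass:
    construct: str
    n_replicates_detected: int
    n_replicates_total: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.n_replicates_detected <= self.n_replicates_total:
            raise ValueError("n_replicates_detected out of range")

    @property
    def high(self) -> bool:
        """Detected in all replicates."""
        return self.n_replicates_detected == self.n_replicates_total


class GappedKmerFeaturizer:
    """Precomputed index machinery for one (l, k) configuration.

    Feature ids are ``comb_index * 4**k + base_code`` where ``comb_index``
    enumerates the C(l, k) informative-position choices and ``base_code`` packs
    the k bases in 2 bits each. With reverse-complement collapsing every id is
    mapped to min(id, id of its reverse complement).
    """

    def __init__(self, params: KmerParams):
        self.params = params
        l, k = params.l, params.k
        self.combs = np.array(list(itertools.combinations(range(l), k)), dtype=np.int64)
        self.n_combs = len(self.combs)
        self.n_codes = 4 ** k
        self.n_features = self.n_combs * self.n_codes
        self._powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        comb_index = {tuple(c): i for i, c in enumerate(map(tuple, self.combs))}
        # reverse complement of comb positions p -> l-1-p, re-sorted
        self._rc_comb = np.array(
            [comb_index[tuple(sorted(l - 1 - p for p in c))] for c in self.combs],
            dtype=np.int64,
        )
        # code = sum_i d_i 4^(k-1-i); its reverse complement is
        # sum_i (3 - d_i) 4^i  (digit order reversed, bases complemented)
        codes = np.arange(self.n_codes, dtype=np.int64)
        rc = np.zeros_like(codes)
        for i in range(k):
            digit = (codes // self._powers[i]) % 4
            rc += (3 - digit) * (4 ** i)
        self._rc_code = rc
        # (l, n_combs) weight matrix: one matmul packs every window into all
        # comb codes at once (codes < 4^k << 2^53, so float64 matmul is exact)
        wmat = np.zeros((l, self.n_combs))
        for ci, comb in enumerate(self.combs):
            for i, p in enumerate(comb):
                wmat[p, ci] = self._powers[i]
        self._wmat = wmat

    def canonicalize(self, ids: np.ndarray) -> np.ndarray:
        comb_idx, code = divmod(ids, self.n_codes)
        rc_ids = self._rc_comb[comb_idx] * self.n_codes + self._rc_code[code]
        return np.minimum(ids, rc_ids)

    def window_feature_ids(self, seq: str) -> np.ndarray:
        """Flat array of one feature id per (valid window, position choice)."""
        l = self.params.l
        enc = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        code = np.full(len(enc), -1, dtype=np.int8)
        for b, v in _BASE_CODE.items():
            code[enc == ord(b)] = v
        if len(code) < l:
            return np.empty(0, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(code, l)
        valid = ~(win < 0).any(axis=1)
        win = win[valid].astype(np.int64)
        if len(win) == 0:
            return np.empty(0, dtype=np.int64)
        codes = (win.astype(np.float64) @ self._wmat).astype(np.int64)
        ids = codes + np.arange(self.n_combs, dtype=np.int64) * self.n_codes
        ids = ids.ravel()
        if self.params.revcomp_collapse:
            ids = self.canonicalize(ids)
        return ids

    def featurize(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Sparse feature counts for one sequence: (feature ids, counts)."""
        ids = self.window_feature_ids(seq)
        if len(ids) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.unique(ids, return_counts=True)

    def matrix(self, seqs: Sequence[str]) -> sparse.csr_matrix:
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for s in seqs:
            ids, counts = self.featurize(s)
            indices.append(ids.astype(np.int32))
            data.append(counts.astype(np.float32))
            indptr.append(indptr[-1] + len(ids))
        return sparse.csr_matrix(
            (
                np.concatenate(data) if data else np.empty(0),
                np.concatenate(indices) if indices else np.empty(0, dtype=np.int32),
                np.asarray(indptr, dtype=np.int64),
            ),
            shape=(len(seqs), self.n_features),
        )


def featurize(seq: str, p: KmerParams | None = None) -> dict[int, int]:
    """Gapped k-mer counts for one sequence as {feature id: count}. Windows
    containing N are skipped; sequences shorter than l give an empty mapping."""
    p = p or KmerParams()
    ids, counts = GappedKmerFeaturizer(p).featurize(seq)
    return dict(zip(ids.tolist(), counts.tolist()))


def feature_to_pattern(
    feature_id: int, p: KmerParams, fz: GappedKmerFeaturizer | None = None
) -> str:
    """Render a feature id as a length-l string with '.' at gapped positions."""
    fz = fz or GappedKmerFeaturizer(p)
    comb_idx, code = divmod(int(feature_id), fz.n_codes)
    positions = fz.combs[comb_idx]
    out = ["."] * p.l
    for i, pos in enumerate(positions):
        out[pos] = _CODE_BASE[(code // int(fz._powers[i])) % 4]
    return "".join(out)


@dataclass
class KmerModel:
    """Linear gapped k-mer scorer: score(seq) = sum_i w_i * x_i(seq)."""

    feature_ids: np.ndarray
    weights: np.ndarray
    intercept: float
    params: KmerParams
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0
    _featurizer: GappedKmerFeaturizer | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("model weights must be finite")

    @property
    def featurizer(self) -> GappedKmerFeaturizer:
        if self._featurizer is None:
            self._featurizer = GappedKmerFeaturizer(self.params)
        return self._featurizer

    def weight_vector(self) -> np.ndarray:
        w = np.zeros(self.featurizer.n_features)
        w[self.feature_ids] = self.weights
        return w

    def top_features(self, n: int = 20) -> list[tuple[str, float]]:
        order = np.argsort(self.weights)[::-1][:n]
        return [
            (feature_to_pattern(int(self.feature_ids[i]), self.params, self.featurizer), float(self.weights[i]))
            for i in order
        ]

    def save(self, path: str | Path) -> None:
        """TSV of (feature id, pattern, weight) with a JSON header line."""
        header = {
            "l": self.params.l, "k": self.params.k, "d": self.params.d,
            "revcomp_collapse": self.params.revcomp_collapse,
            "intercept": self.intercept,
            "n_pos": self.n_pos, "n_neg": self.n_neg, "seed": self.seed,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fz = self.featurizer
            for fid, w in zip(self.feature_ids, self.weights):
                fh.write(f"{int(fid)}\t{feature_to_pattern(int(fid), self.params, fz)}\t{w:.10g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerModel":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            fids, ws = [], []
            for line in fh:
                f = line.split("\t")
                fids.append(int(f[0]))
                ws.append(float(f[2]))
        params = KmerParams(
            l=header["l"], k=header["k"], d=header["d"],
            revcomp_collapse=header["revcomp_collapse"],
        )
        return cls(
            feature_ids=np.asarray(fids, dtype=np.int64),
            weights=np.asarray(ws),
            intercept=header["intercept"],
            params=params,
            n_pos=header["n_pos"], n_neg=header["n_neg"], seed=header["seed"],
        )


def train(
    pos: Sequence[str],
    neg: Sequence[str],
    p: KmerParams | None = None,
    seed: int = 0,
    alpha: float = 100.0,
    iter_lim: int = 100,
) -> KmerModel:
    """Fit an L2-regularized linear model on gapped k-mer counts (labels +1/-1).

    The explicit-feature ridge fit (via sparse LSQR, penalty alpha on the
    squared weight norm) replaces the original kernel SVM; the scoring form —
    a weighted sum of gapped k-mer counts — is unchanged. The fit is
    deterministic; ``seed`` is recorded as training metadata.
    """
    from scipy.sparse.linalg import lsqr

    p = p or KmerParams()
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    fz = GappedKmerFeaturizer(p)
    X = fz.matrix(list(pos) + list(neg))
    n_pos = len(pos)
    if X.indptr[n_pos] == 0 or X.indptr[-1] == X.indptr[n_pos]:
        raise ValueError("a class has zero usable windows")
    y = np.concatenate(
        [np.ones(n_pos, dtype=np.float32), -np.ones(len(neg), dtype=np.float32)]
    )
    w = lsqr(X, y, damp=float(np.sqrt(alpha)), atol=1e-6, btol=1e-6, iter_lim=iter_lim)[0]
    nz = np.flatnonzero(w)
    return KmerModel(
        feature_ids=nz.astype(np.int64),
        weights=w[nz].astype(np.float64),
        intercept=0.0,
        params=p,
        n_pos=n_pos,
        n_neg=len(neg),
        seed=seed,
        _featurizer=fz,
    )


def score(model: KmerModel, seq: str) -> float:
    """Linear score sum_i w_i x_i(seq); 0 for sequences with no usable window.
    The intercept is deliberately not added: the score is the pure weighted
    feature count, as serialized."""
    ids, counts = model.featurizer.featurize(seq)
    if len(ids) == 0:
        return 0.0
    w = np.zeros(len(ids))
    order = np.argsort(model.feature_ids)
    sorted_fids = model.feature_ids[order]
    pos = np.searchsorted(sorted_fids, ids)
    pos_ok = (pos < len(sorted_fids))
    match = np.zeros(len(ids), dtype=bool)
    match[pos_ok] = sorted_fids[pos[pos_ok]] == ids[pos_ok]
    w[match] = model.weights[order][pos[match]]
    return float(np.dot(w, counts))


def score_many(model: KmerModel, seqs: Sequence[str]) -> np.ndarray:
    X = model.featurizer.matrix(seqs)
    return np.asarray(X @ model.weight_vector()).ravel()


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability that a random positive outscores a random negative, ties
    counting one half (Mann-Whitney U normalization)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def top_decile_enrichment(
    scores: dict[str, float],
    classes: Sequence[ExpressionClass],
    p: KmerParams | None = None,
) -> float:
    """Enrichment of the high expression class (RNA detected in all
    replicates) among the top ``top_frac`` of constructs by score, relative to
    the overall high fraction. NaN (flagged) when no construct is high."""
    p = p or KmerParams()
    if len(classes) < 10:
        raise ValueError("need at least 10 constructs")
    high = {c.construct: c.high for c in classes}
    ids = [c.construct for c in classes]
    missing = [i for i in ids if i not in scores]
    if missing:
        raise KeyError(f"constructs missing scores: {missing[:3]}")
    overall = float(np.mean([high[i] for i in ids]))
    if overall == 0.0:
        return float("nan")
    n_top = max(1, int(len(ids) * p.top_frac))
    ranked = sorted(ids, key=lambda i: (-scores[i], i))[:n_top]
    top_frac_high = float(np.mean([high[i] for i in ranked]))
    return top_frac_high / overall
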