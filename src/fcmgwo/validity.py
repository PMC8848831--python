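"""Cluster-validity indices and paired-comparison statistics.

Two families of indices score a fuzzy segmentation.  The first uses only the
membership matrix: the partition coefficient V_pc (mean squared membership,
1 for crisp partitions, 1/c for maximally fuzzy ones; higher is better) and
the partition entropy V_pe (mean membership entropy, 0 for crisp partitions;
lower is better).  The second uses the data together with hard labels: the
Davies-Bouldin index (average worst-case ratio of within-cluster scatter to
between-centroid separation; lower is better) and the Calinski-Harabasz
index (between- to within-cluster variance ratio scaled by degrees of
freedom; higher is better).

Two segmentation methods run on the same set of images are compared per
index with a paired Student t test on the per-image index differences, after
a Shapiro-Wilk normality check on those differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .fcm import as_feature_matrix
from .pipeline import SegmentationConfig, segment_image

__all__ = [
    "UndefinedIndexError",
    "DegenerateTestError",
    "ValidityReport",
    "ComparisonReport",
    "partition_coefficient",
    "partition_entropy",
    "davies_bouldin",
    "calinski_harabasz",
    "compute_validity",
    "two_sided_t_pvalue",
    "paired_t_test",
    "compare_methods",
]


class UndefinedIndexError(ValueError):
    """The index is undefined for this labeling (e.g. a single cluster)."""


class DegenerateTestError(ValueError):
    """Paired differences have zero variance but are not all zero."""


@dataclass
class ValidityReport:
    vpc: float
    vpe: float
    db: float
    ch: float
    n: int
    c: int

    def as_dict(self) -> dict:
        return {"vpc": self.vpc, "vpe": self.vpe, "db": self.db, "ch": self.ch,
                "n": self.n, "c": self.c}


@dataclass
class ComparisonReport:
    index_name: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    pairs: list[tuple[float, float]] = field(default_factory=list)
    shapiro_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "pairs": [list(p) for p in self.pairs],
            "shapiro_p": self.shapiro_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            index_name=d["index_name"],
            t_statistic=d["t_statistic"],
            degrees_of_freedom=d["degrees_of_freedom"],
            p_value=d["p_value"],
            pairs=[tuple(p) for p in d["pairs"]],
            shapiro_p=d.get("shapiro_p"),
        )

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    @classmethod
    def from_json(cls, s: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(s))


def _check_u(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[0] < 1:
        raise ValueError(f"membership matrix must be 2-D, got shape {u.shape}")
    return u


def partition_coefficient(u: np.ndarray) -> float:
    """V_pc = (1/n) sum_ij u_ij^2; in [1/c, 1], 1 iff crisp."""
    u = _check_u(u)
    return float(np.sum(u**2) / u.shape[0])


def partition_entropy(u: np.ndarray, log_base: float | None = None) -> float:
    """V_pe = -(1/n) sum_ij u_ij log u_ij with 0 log 0 = 0.

    Natural log by default; pass ``log_base`` (e.g. ``c``) to normalize the
    maximum to 1.
    """
    u = _check_u(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0.0, u * np.log(u), 0.0)
    vpe = -float(terms.sum() / u.shape[0])
    if log_base is not None:
        vpe /= np.log(log_base)
    return vpe


def _check_labeled(data: np.ndarray, labels: np.ndarray):
    X = as_feature_matrix(data)
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != X.shape[0]:
        raise ValueError(f"{labels.shape[0]} labels for {X.shape[0]} points")
    uniq, encoded = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise UndefinedIndexError("index undefined with fewer than 2 non-empty clusters")
    return X, encoded, uniq.size


def davies_bouldin(data: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index on crisp labels; lower is better."""
    X, encoded, _ = _check_labeled(data, labels)
    return float(davies_bouldin_score(X, encoded))


def calinski_harabasz(data: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index on crisp labels; higher is better."""
    X, encoded, c = _check_labeled(data, labels)
    if X.shape[0] <= c:
        raise UndefinedIndexError(f"need more points ({X.shape[0]}) than clusters ({c})")
    return float(calinski_harabasz_score(X, encoded))


def compute_validity(data: np.ndarray, u: np.ndarray, labels: np.ndarray) -> ValidityReport:
    """All four indices for one segmentation."""
    u = _check_u(u)
    return ValidityReport(
        vpc=partition_coefficient(u),
        vpe=partition_entropy(u),
        db=davies_bouldin(data, labels),
        ch=calinski_harabasz(data, labels),
        n=u.shape[0],
        c=u.shape[1],
    )


def two_sided_t_pvalue(t: float, df: int) -> float:
    """Two-sided Student-t tail probability 2 P(T_df >= |t|)."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def paired_t_test(x, y, index_name: str = "") -> ComparisonReport:
    """Paired t test on differences d = x - y; df = n - 1.

    All-zero differences give t = 0, p = 1; nonzero differences with zero
    variance have no defined t statistic and raise
    :class:`DegenerateTestError`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if np.all(d == 0.0):
            t = 0.0
        else:
            raise DegenerateTestError("nonzero differences with zero variance")
    else:
        t = float(np.mean(d) / (sd / np.sqrt(n)))
    return ComparisonReport(
        index_name=index_name,
        t_statistic=t,
        degrees_of_freedom=n - 1,
        p_value=two_sided_t_pvalue(t, n - 1),
        pairs=list(zip(x.tolist(), y.tolist())),
    )


def _preprocessed_pixels(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    from .imaging import preprocess

    return preprocess(img, cfg.preprocess).reshape(-1, 1).astype(float)


def compare_methods(
    images,
    cfg: SegmentationConfig | None = None,
    methods: tuple[str, str] = ("fcm", "fcmgwo"),
) -> dict[str, ComparisonReport]:
    """Segment each image with both methods and paired-t test each index.

    Returns one :class:`ComparisonReport` per index (vpc, vpe, db, ch) with
    pairs ordered as ``(methods[0], methods[1])``.  A Shapiro-Wilk normality
    p-value on the paired differences is attached when there are at least 3
    images (delegated to scipy; only its role in the workflow is reproduced
    here).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    images = list(images)
    if len(images) < 2:
        raise ValueError(f"need at least 2 images, got {len(images)}")

    per_index: dict[str, dict[str, list[float]]] = {
        name: {m: [] for m in ("a", "b")} for name in ("vpc", "vpe", "db", "ch")
    }
    for img in images:
        for slot, method in zip(("a", "b"), methods):
            run_cfg = SegmentationConfig(fcm=cfg.fcm, gwo=cfg.gwo,
                                         preprocess=cfg.preprocess, method=method)
            res = segment_image(img, run_cfg)
            pixels = _preprocessed_pixels(img, run_cfg)
            report = compute_validity(pixels, res.memberships, res.labels.ravel())
            for name in per_index:
                per_index[name][slot].append(getattr(report, name))

    out: dict[str, ComparisonReport] = {}
    for name, vals in per_index.items():
        report = paired_t_test(vals["a"], vals["b"], index_name=name)
        d = np.asarray(vals["a"]) - np.asarray(vals["b"])
        if d.size >= 3 and np.ptp(d) > 0:
            report.shapiro_p = float(stats.shapiro(d).pvalue)
        out[name] = report
    return out
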