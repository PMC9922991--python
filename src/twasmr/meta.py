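"""Weighted inverse-normal p-value meta-analysis and bidirectional replication.

Replication cohorts are combined Stouffer-style: each study's two-sided
p becomes a signed one-sided z carrying the effect direction, weighted
by the square root of study size (weights normalised so their squares
sum to one). Replication between a discovery set and the combined
replication set uses a Bonferroni threshold over the discovery-significant
features actually testable in replication; bidirectional replication is
the intersection of the two directed replication sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "ReplicationReport",
    "inverse_normal_meta",
    "meta_analyze",
    "replicate",
    "bidirectional_replication",
]

_P_FLOOR = 1e-300


@dataclass
class MetaResult:
    """Combined statistic for one feature across studies."""

    feature_id: str
    z_s: np.ndarray
    w_s: np.ndarray
    n_s: np.ndarray
    combined_z: float
    combined_p: float
    direction_consistent: bool


@dataclass
class ReplicationReport:
    """Outcome of one directed discovery -> replication pass."""

    discovery_set: pd.DataFrame          # feature_id, q
    testable_count: int
    threshold: float
    replicated_set: list[str]
    bidirectional_set: list[str] = field(default_factory=list)


def _clamp_p(p: np.ndarray) -> np.ndarray:
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        log.warning("%d p-values at 0 or 1 clamped before inverse-normal", bad.sum())
    return np.clip(p, _P_FLOOR, 1.0 - 1e-16)


def inverse_normal_meta(
    p,
    signs,
    n,
    *,
    feature_id: str = "",
    weight_scheme: str = "sqrt-n",
    signed: bool = True,
) -> MetaResult:
    """Combine per-study two-sided p-values for one feature.

    z_s = sign(beta_s) * Phi^-1(1 - p_s/2); weights proportional to
    sqrt(n_s) (default) or n_s, normalised so sum w^2 = 1; combined
    z = sum w_s z_s, combined p two-sided normal. With ``signed=False``
    all z are taken positive (pure evidence combination, no direction).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    signs = np.sign(np.atleast_1d(np.asarray(signs, dtype=float)))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if not (p.size == signs.size == n.size) or p.size == 0:
        raise ValueError("p, signs and n must be non-empty and equally long")
    if np.any(n <= 0):
        raise ValueError("study sizes must be positive")
    p = _clamp_p(p)
    signs = np.where(signs == 0, 1.0, signs)

    z = stats.norm.isf(p / 2.0)
    if signed:
        z = signs * z
    if weight_scheme == "sqrt-n":
        raw = np.sqrt(n)
    elif weight_scheme == "n":
        raw = n
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    w = raw / np.sqrt(np.sum(raw**2))
    combined_z = float(np.sum(w * z))
    combined_p = float(min(2.0 * stats.norm.sf(abs(combined_z)), 1.0))
    combined_p = max(combined_p, _P_FLOOR)
    return MetaResult(
        feature_id=feature_id,
        z_s=z,
        w_s=w,
        n_s=n,
        combined_z=combined_z,
        combined_p=combined_p,
        direction_consistent=bool(len(set(np.sign(z[z != 0]))) <= 1),
    )


def meta_analyze(
    studies: list[pd.DataFrame],
    *,
    weight_scheme: str = "sqrt-n",
    signed: bool = True,
) -> pd.DataFrame:
    """Feature-wise inverse-normal meta-analysis of association tables.

    Each study table needs columns feature_id, beta, p, n. Only
    features present in every study are combined (the replication
    universe). Vectorised across features.
    """
    if not studies:
        raise ValueError("at least one study required")
    common = set(studies[0]["feature_id"])
    for s in studies[1:]:
        common &= set(s["feature_id"])
    features = sorted(common)
    if not features:
        return pd.DataFrame(
            columns=["feature_id", "combined_z", "combined_p", "direction_consistent"]
        )
    S = len(studies)
    P = np.empty((S, len(features)))
    B = np.empty((S, len(features)))
    N = np.empty((S, len(features)))
    for i, s in enumerate(studies):
        s = s.set_index("feature_id").loc[features]
        P[i] = s["p"].to_numpy(dtype=float)
        B[i] = s["beta"].to_numpy(dtype=float)
        N[i] = s["n"].to_numpy(dtype=float)
    P = _clamp_p(P)
    Z = stats.norm.isf(P / 2.0)
    if signed:
        Z = np.where(np.sign(B) == 0, 1.0, np.sign(B)) * Z
    raw = np.sqrt(N) if weight_scheme == "sqrt-n" else N
    if weight_scheme not in ("sqrt-n", "n"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    W = raw / np.sqrt((raw**2).sum(axis=0))
    cz = (W * Z).sum(axis=0)
    cp = np.clip(2.0 * stats.norm.sf(np.abs(cz)), _P_FLOOR, 1.0)
    consistent = np.all(np.sign(Z) == np.sign(Z[0]), axis=0) | np.any(Z == 0, axis=0)
    out = pd.DataFrame(
        {
            "feature_id": features,
            "combined_z": cz,
            "combined_p": cp,
            "direction_consistent": consistent,
            "n": N.sum(axis=0),
        }
    )
    return out.sort_values(["combined_p", "feature_id"], kind="stable").reset_index(
        drop=True
    )


def replicate(
    discovery: pd.DataFrame,
    replication_meta: pd.DataFrame,
    alpha: float = 0.05,
    *,
    discovery_q: float = 0.05,
) -> ReplicationReport:
    """Directed replication of discovery-significant features.

    m = number of features significant in discovery (q < ``discovery_q``)
    and present in the replication universe; a feature replicates iff
    its combined replication p is strictly below alpha/m.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    disc_sig = discovery.loc[discovery["q"] < discovery_q, ["feature_id", "q"]]
    universe = set(replication_meta["feature_id"])
    testable = disc_sig[disc_sig["feature_id"].isin(universe)]
    m = len(testable)
    if m == 0:
        log.warning("no discovery-significant features testable in replication")
        return ReplicationReport(disc_sig, 0, np.nan, [])
    threshold = alpha / m
    meta_p = replication_meta.set_index("feature_id")["combined_p"]
    replicated = sorted(
        f for f in testable["feature_id"] if meta_p[f] < threshold
    )
    log.info(
        "replicate: %d discovery-significant, %d testable, threshold %.3g, "
        "%d replicated", len(disc_sig), m, threshold, len(replicated),
    )
    return ReplicationReport(disc_sig, m, threshold, replicated)


def bidirectional_replication(
    report_ab: ReplicationReport, report_ba: ReplicationReport
) -> list[str]:
    """Features replicating in both directions (set intersection)."""
    both = sorted(set(report_ab.replicated_set) & set(report_ba.replicated_set))
    report_ab.bidirectional_set = both
    report_ba.bidirectional_set = both
    return both
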