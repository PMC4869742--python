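"""Per-subset pairwise Pearson correlations and the Fisher z transform.

For one sample subset, every unordered metabolite pair gets a Pearson r
computed over pairwise-complete observations, the pairwise sample count n,
and the variance-stabilizing Fisher transform z = atanh(r), whose sampling
variance is approximately 1/(n−3). Pairs that cannot support the downstream
change test — too few complete observations, zero variance, or |r| = 1
(infinite z) — are excluded with a recorded reason rather than clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import MetaboliteRegistry, MetaboliteTable
from .errors import InsufficientSamplesError, SaturatedCorrelationError

logger = logging.getLogger(__name__)

#: Minimum pairwise-complete count for a retained pair. The change test
#: needs n − 3 > 0; one extra observation is required for sanity.
DEFAULT_N_MIN = 4

#: |r| within this distance of 1 is treated as saturated (z would overflow).
_SATURATION_EPS = 1e-12


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r) = ½·ln((1+r)/(1−r)).

    Strictly increasing and odd; requires |r| < 1. Accepts scalars or
    arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise SaturatedCorrelationError(
            "fisher_z requires |r| < 1; got a saturated correlation"
        )
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out

def fisher_z_inverse(z):
    """Inverse transform, r = tanh(z) ∈ (−1, 1)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out.item() if out.ndim == 0 else out


@dataclass
class CorrelationSet:
    """All retained pairwise correlations for one sample subset.

    ``pairs`` is indexed by (metabolite_i, metabolite_j) with i < j in code
    order and has columns ``r``, ``n``, ``z``, ``flag`` (empty string for
    clean pairs, ``"saturated"`` for |r| = 1 pairs, which keep their r but
    carry z = NaN and are excluded from all z-based analyses).
    ``excluded`` records dropped pairs with the reason.
    """

    label: str
    pairs: pd.DataFrame
    n_samples: int
    excluded: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    roster: tuple[str, ...] = ()

    @property
    def metabolites(self) -> list[str]:
        """The metabolite roster the set was computed over (falls back to
        the codes appearing in retained pairs for reconstructed sets)."""
        if self.roster:
            return sorted(self.roster)
        codes = set()
        for i, j in self.pairs.index:
            codes.add(i)
            codes.add(j)
        return sorted(codes)

    def usable(self) -> pd.DataFrame:
        """Pairs with a finite z (saturated pairs dropped)."""
        return self.pairs[self.pairs["flag"] == ""]

    def get(self, met_i: str, met_j: str) -> pd.Series:
        key = (met_i, met_j) if met_i < met_j else (met_j, met_i)
        return self.pairs.loc[key]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: subset, metabolite_i, metabolite_j, r, n, z, flag."""
        out = self.pairs.reset_index(names=["metabolite_i", "metabolite_j"])
        out.insert(0, "subset", self.label)
        return out


def correlation_sets_from_long(frame: pd.DataFrame) -> dict[str, CorrelationSet]:
    """Rebuild per-subset :class:`CorrelationSet` objects from long format.

    Accepts the layout written by :meth:`CorrelationSet.to_long_frame`
    (and of transcribed per-subset correlation listings in the same shape):
    columns ``subset, metabolite_i, metabolite_j, r`` with optional ``n``,
    ``z``, ``flag``. Missing z is recomputed from r; missing n is NaN.
    """
    required = {"subset", "metabolite_i", "metabolite_j", "r"}
    if not required.issubset(frame.columns):
        raise ValueError(f"long-format frame needs columns {sorted(required)}")
    out: dict[str, CorrelationSet] = {}
    for label, grp in frame.groupby("subset", sort=True):
        pairs = grp.copy()
        ij = np.sort(pairs[["metabolite_i", "metabolite_j"]].to_numpy(), axis=1)
        pairs["metabolite_i"], pairs["metabolite_j"] = ij[:, 0], ij[:, 1]
        if "z" not in pairs.columns:
            r = pairs["r"].to_numpy(float)
            pairs["z"] = np.where(np.abs(r) < 1, np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), np.nan)
        if "n" not in pairs.columns:
            pairs["n"] = np.nan
        if "flag" not in pairs.columns:
            pairs["flag"] = np.where(np.abs(pairs["r"]) >= 1, "saturated", "")
        pairs["flag"] = pairs["flag"].fillna("")
        pairs = pairs.set_index(["metabolite_i", "metabolite_j"]).sort_index()
        out[str(label)] = CorrelationSet(
            str(label), pairs[["r", "n", "z", "flag"]],
            n_samples=int(pairs["n"].max()) if pairs["n"].notna().any() else 0,
        )
    return out


def pairwise_correlations(
    table: MetaboliteTable,
    subset: Sequence[str],
    registry: MetaboliteRegistry | None = None,
    label: str = "subset",
    n_min: int = DEFAULT_N_MIN,
) -> CorrelationSet:
    """Pearson r over pairwise-complete observations for one subset.

    Metabolites flagged as excluded in the registry (the uncharacterized
    ``B``) never enter pairing. Pairs with fewer than ``n_min`` complete
    observations or zero variance in either member are excluded with a
    logged reason; |r| = 1 pairs are retained but flagged ``saturated``.
    """
    registry = registry or table.registry
    subset = list(subset)
    if len(subset) < n_min:
        raise InsufficientSamplesError(
            f"subset {label!r} has {len(subset)} samples; need at least {n_min}"
        )
    codes = [m for m in table.metabolites if not registry.is_excluded(m)]
    X = table.values.loc[subset, codes].to_numpy(dtype=float)

    mask = np.isfinite(X)
    Xz = np.where(mask, X, 0.0)
    m = mask.astype(float)
    n_pair = m.T @ m                       # pairwise-complete counts
    s1 = Xz.T @ m                          # sum of x over joint support
    s2 = (Xz ** 2).T @ m                   # sum of x^2 over joint support
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s1 * s1.T / n_pair
        var_i = s2 - s1 ** 2 / n_pair      # var of metabolite i on joint support
        var_j = var_i.T
        denom = np.sqrt(var_i * var_j)
        r_mat = cov / denom

    rows, excluded = [], []
    for a in range(len(codes)):
        for b in range(a + 1, len(codes)):
            pair = (codes[a], codes[b])
            n = int(n_pair[a, b])
            if n < n_min:
                excluded.append((pair, f"n={n} < n_min={n_min}"))
                continue
            if denom[a, b] == 0 or not np.isfinite(denom[a, b]):
                excluded.append((pair, "zero variance on joint support"))
                continue
            r = float(np.clip(r_mat[a, b], -1.0, 1.0))
            if abs(r) >= 1 - _SATURATION_EPS:
                rows.append((pair, float(np.sign(r)), n, np.nan, "saturated"))
                continue
            rows.append((pair, r, n, float(np.arctanh(r)), ""))

    index = pd.MultiIndex.from_tuples(
        [p for p, *_ in rows], names=["metabolite_i", "metabolite_j"]
    ) if rows else pd.MultiIndex.from_tuples([], names=["metabolite_i", "metabolite_j"])
    pairs = pd.DataFrame(
        [(r, n, z, flag) for _, r, n, z, flag in rows],
        index=index, columns=["r", "n", "z", "flag"],
    ).astype({"r": float, "n": int, "z": float, "flag": str}) if rows else pd.DataFrame(
        columns=["r", "n", "z", "flag"], index=index
    )
    for pair, reason in excluded:
        logger.debug("subset %s: excluded pair %s (%s)", label, pair, reason)
    logger.info(
        "subset %s: %d samples, %d retained pairs, %d excluded",
        label, len(subset), len(pairs), len(excluded),
    )
    return CorrelationSet(label, pairs, len(subset), excluded, tuple(codes))
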