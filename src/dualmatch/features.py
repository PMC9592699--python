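"""Per-patient deep features and Mann-Whitney screening.

After the target network is reparameterized, every collapsed convolution
kernel acts as one feature detector: each of a patient's n slice images
is forwarded through the network, the kernel's output map is global-mean
pooled to one value, and the n values are averaged.  A patient therefore
yields an L-vector, L being the network's reparameterized-kernel count.

Features are screened with the two-sided Mann-Whitney U test (midrank
ties; tie-corrected normal approximation with continuity correction, or
exact permutation enumeration for pooled n <= 12); a feature is kept when
p < 0.05.  No multiple-testing correction is applied by default,
Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dbb import count_feature_channels  # noqa: F401  (re-exported surface)
from .nn import Tensor

EXACT_MAX_N = 12


def extract_patient_features(reparam_net, patient) -> np.ndarray:
    """L-vector of one patient: per slice, global mean pooling of every
    reparameterized kernel's pre-activation output; then the arithmetic
    mean over slices.  The vector is also stored on the record."""
    if not patient.slices:
        raise ValueError("patient has no slices")
    per_slice = []
    for sl in patient.slices:
        maps = reparam_net.feature_maps(Tensor(sl[None].astype(np.float32)))
        pooled = np.concatenate([m.data.mean(axis=(2, 3))[0] for m in maps])
        per_slice.append(pooled)
    vec = np.mean(per_slice, axis=0)
    patient.features = vec
    return vec


def extract_cohort_features(reparam_net, cohort) -> pd.DataFrame:
    """FeatureMatrix rows for a cohort, indexed by patient id; column
    names encode (convolution layer, kernel index)."""
    rows = [extract_patient_features(reparam_net, rec) for rec in cohort]
    l_total = len(rows[0])
    names = _feature_names(reparam_net, l_total)
    return pd.DataFrame(rows, index=[rec.patient_id for rec in cohort],
                        columns=names)


def _feature_names(reparam_net, l_total):
    names = []
    if hasattr(reparam_net, "convs"):
        for li, conv in enumerate(reparam_net.convs):
            for ki in range(conv.weight.shape[0]):
                names.append(f"L{li:02d}_k{ki:03d}")
    if len(names) != l_total:
        names = [f"f{i:04d}" for i in range(l_total)]
    return names


# ----------------------------------------------------------- Mann-Whitney

def mann_whitney_u(group1: np.ndarray, group0: np.ndarray):
    """Two-sided Mann-Whitney U for group1 vs group0.

    U counts pairs where group1 exceeds group0, with half credit for
    ties (midranks).  Exact permutation p when n1+n0 <= EXACT_MAX_N,
    otherwise tie-corrected normal approximation with continuity
    correction.  Returns (U, p) with p in (0, 1]."""
    g1 = np.asarray(group1, dtype=float)
    g0 = np.asarray(group0, dtype=float)
    n1, n0 = len(g1), len(g0)
    if n1 < 1 or n0 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g0])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n0 / 2.0

    if n1 + n0 <= EXACT_MAX_N:
        # enumerate all assignments of the pooled midranks to group 1
        dev_obs = abs(u - mu)
        n = n1 + n0
        hits = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / comb(n, n1)
        return float(u), float(min(max(p, np.finfo(float).tiny), 1.0))

    n = n1 + n0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1.0))
    var = n1 * n0 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(u), float(min(max(p, np.finfo(float).tiny), 1.0))


@dataclass
class ScreenResult:
    """Per-feature U statistic, two-sided p value, and selection flag."""

    table: pd.DataFrame  # columns: u, p, selected

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def mann_whitney_screen(features: pd.DataFrame, labels: np.ndarray,
                        alpha: float = 0.05, bh_correction: bool = False) -> ScreenResult:
    """Screen every feature column by a two-sided Mann-Whitney test of
    class 1 vs class 0; selected when p < alpha (optionally after
    Benjamini-Hochberg adjustment)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for screening")
    mask1 = labels == 1
    us, ps = [], []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        u, p = mann_whitney_u(vals[mask1], vals[~mask1])
        us.append(u)
        ps.append(p)
    ps = np.array(ps)
    if bh_correction:
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        m = len(ps)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            adj[i] = running
        sel = adj < alpha
    else:
        sel = ps < alpha
    table = pd.DataFrame({"u": us, "p": ps, "selected": sel},
                         index=features.columns)
    return ScreenResult(table)


def assemble_feature_table(deep_features: pd.DataFrame,
                           clinical_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join screened deep features with clinical/CT-finding columns on
    patient id; categorical clinical columns are one-hot encoded."""
    if clinical_table is None:
        return deep_features.copy()
    if set(deep_features.index) != set(clinical_table.index):
        raise ValueError("patient ids of deep and clinical tables do not match")
    clin = clinical_table.loc[deep_features.index]
    cat_cols = [c for c in clin.columns if clin[c].dtype == object
                or str(clin[c].dtype) == "category"]
    clin = pd.get_dummies(clin, columns=cat_cols, dtype=float)
    return pd.concat([deep_features, clin], axis=1)


def zscore_fit(train: pd.DataFrame):
    """Column means/SDs on the training cohort (SD floor 1e-12)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0).replace(0.0, 1.0).clip(lower=1e-12)
    return mu, sd


def zscore_apply(table: pd.DataFrame, mu, sd) -> pd.DataFrame:
    return (table - mu) / sd
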