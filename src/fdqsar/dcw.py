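"""SMILES correlation-weight optimal descriptor (DCW).

A compound's DCW is the sum, over its SMILES attribute multiset, of
per-attribute correlation weights.  Attributes are single tokens (Sk) and
adjacent-token pairs (SSk, canonicalized by lexicographic order so that the
pair is direction-independent).  Weights start at 1 for attributes occurring
in at least T distinct active-training compounds (others are blocked at 0)
and are optimized by a seeded coordinate-wise Monte Carlo hill-climb against
the squared Pearson correlation of DCW with the endpoint over the active and
passive training groups.  Calibration-set r² recorded after each epoch picks
the returned snapshot (early stopping against overfitting); the final
prediction line C0 + C1·DCW is fit on the active training group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .smiles_graph import tokenize

# an attribute is (kind, text); pair text joins the two tokens, sorted, with '+'
AttributeKey = tuple[str, str]


@dataclass
class CorrelationWeights:
    """Attribute → weight table with occurrence threshold T and epoch budget N."""

    weights: dict[AttributeKey, float]
    threshold: int = 1
    epochs: int = 0
    seed: int = 0

    def get(self, key: AttributeKey) -> float:
        return self.weights.get(key, 0.0)


@dataclass
class DCWModel:
    """Optimized weights plus the calibration line prediction = C0 + C1·DCW."""

    weights: CorrelationWeights
    c0: float
    c1: float
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def dcw(self, smiles: str) -> float:
        return dcw_value(smiles, self.weights)

    def predict(self, smiles: str) -> float:
        return self.c0 + self.c1 * self.dcw(smiles)


def extract_attributes(smiles: str) -> Counter:
    """Multiset of single-token and adjacent-pair attributes of a SMILES."""
    tokens = tokenize(smiles)
    attrs: Counter = Counter()
    for t in tokens:
        attrs[("single", t)] += 1
    for a, b in zip(tokens, tokens[1:]):
        lo, hi = sorted((a, b))
        attrs[("pair", f"{lo}+{hi}")] += 1
    return attrs


def build_vocabulary(
    training_smiles: list[str], T: int = 1, epochs: int = 0, seed: int = 0
) -> CorrelationWeights:
    """Initial weights: 1.0 for attributes in ≥ T distinct training compounds.

    Attributes below the threshold are blocked: absent from the table, hence
    weight exactly 0 and never perturbed by the optimizer.
    """
    if T < 1:
        raise ValueError("occurrence threshold T must be >= 1")
    if not training_smiles:
        raise ValueError("active-training SMILES list is empty")
    presence: Counter = Counter()
    for s in training_smiles:
        presence.update(set(extract_attributes(s)))
    weights = {key: 1.0 for key, n in sorted(presence.items()) if n >= T}
    return CorrelationWeights(weights=weights, threshold=T, epochs=epochs, seed=seed)


def dcw_value(smiles: str, w: CorrelationWeights) -> float:
    """Sum of weight × multiplicity over the compound's attributes.

    Attributes outside the weight table (blocked or unseen) contribute 0.
    """
    return float(
        sum(w.get(key) * mult for key, mult in extract_attributes(smiles).items())
    )


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when x has no variance."""
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return 0.0
    return float(((sx * sy).sum() / denom) ** 2)


def optimize_weights(
    smiles_by_group: dict[str, list[str]],
    endpoint_by_group: dict[str, np.ndarray],
    T: int = 1,
    N: int = 20,
    delta: float = 0.1,
    seed: int = 0,
) -> DCWModel:
    """Monte Carlo hill-climb of correlation weights against an endpoint.

    ``smiles_by_group`` / ``endpoint_by_group`` hold the four split groups
    (keys ``active``, ``passive``, ``calibration``, ``validation``; the
    first two drive the objective, calibration drives early stopping).
    The objective — squared Pearson correlation of DCW with the endpoint
    over active ∪ passive — increases strictly at every accepted move.
    (T, N, delta, seed) fully determine the result.
    """
    for grp in ("active", "calibration"):
        if not smiles_by_group.get(grp):
            raise ValueError(f"{grp} group is empty")
    weights = build_vocabulary(
        smiles_by_group["active"], T=T, epochs=N, seed=seed
    )
    keys = sorted(weights.weights)
    if not keys:
        raise ValueError("no active attributes above the occurrence threshold")

    # attribute count matrices per group (n_compounds × n_active_attributes)
    key_index = {k: j for j, k in enumerate(keys)}
    counts: dict[str, np.ndarray] = {}
    for grp, smiles_list in smiles_by_group.items():
        A = np.zeros((len(smiles_list), len(keys)))
        for i, s in enumerate(smiles_list):
            for key, mult in extract_attributes(s).items():
                j = key_index.get(key)
                if j is not None:
                    A[i, j] = mult
        counts[grp] = A

    y_obj = np.concatenate(
        [
            np.asarray(endpoint_by_group["active"], dtype=float),
            np.asarray(endpoint_by_group.get("passive", []), dtype=float),
        ]
    )
    A_obj = (
        np.vstack([counts["active"], counts["passive"]])
        if len(smiles_by_group.get("passive", []))
        else counts["active"]
    )
    if np.ptp(y_obj) == 0:
        raise ValueError("endpoint has zero variance on the training groups")
    y_cal = np.asarray(endpoint_by_group["calibration"], dtype=float)
    A_cal = counts["calibration"]

    rng = np.random.default_rng(seed)
    w = np.ones(len(keys))
    dcw_obj = A_obj @ w
    dcw_cal = A_cal @ w
    objective = _r2(dcw_obj, y_obj)
    trace = [objective]

    best_w = w.copy()
    best_cal_r2 = _r2(dcw_cal, y_cal)
    best_epoch = 0

    for epoch in range(N):
        for j in rng.permutation(len(keys)):
            u = 1.0 - rng.random()  # Uniform(0, 1]
            # propose weight ± delta*u: evaluate both signs, keep the better
            best_step, best_objective = 0.0, objective
            for step in (delta * u, -delta * u):
                cand = _r2(dcw_obj + step * A_obj[:, j], y_obj)
                if cand > best_objective:
                    best_step, best_objective = step, cand
            if best_step != 0.0:
                assert best_objective > trace[-1]  # strict monotone objective
                w[j] += best_step
                dcw_obj = dcw_obj + best_step * A_obj[:, j]
                dcw_cal = dcw_cal + best_step * A_cal[:, j]
                objective = best_objective
                trace.append(objective)
        cal_r2 = _r2(dcw_cal, y_cal)
        if cal_r2 > best_cal_r2:
            best_cal_r2 = cal_r2
            best_w = w.copy()
            best_epoch = epoch + 1

    weights.weights = {k: float(best_w[j]) for j, k in enumerate(keys)}

    # calibration line on the active training group
    y_act = np.asarray(endpoint_by_group["active"], dtype=float)
    d_act = counts["active"] @ best_w
    X = np.column_stack([np.ones_like(d_act), d_act])
    (c0, c1), *_ = np.linalg.lstsq(X, y_act, rcond=None)

    stats: dict[str, dict[str, float]] = {}
    for grp, A in counts.items():
        y_grp = np.asarray(endpoint_by_group[grp], dtype=float)
        if len(y_grp) == 0:
            continue
        pred = c0 + c1 * (A @ best_w)
        stats[grp] = {
            "r2": _r2(pred, y_grp),
            "rmse": float(np.sqrt(np.mean((pred - y_grp) ** 2))),
        }

    return DCWModel(
        weights=weights,
        c0=float(c0),
        c1=float(c1),
        stats=stats,
        objective_trace=trace,
        best_epoch=best_epoch,
    )
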