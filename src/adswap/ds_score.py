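"""The DS score: swap-signature factors, penalty model, training, metrics.

The score gates a normalized structural similarity S₀ (the virtual Q-score)
by hinge existence (η ∈ {0,1}) and an exponential penalty built from three
swap-specific factors measured after superposing the main domains:

* γ_θ — normalized angular difference of the swapped domains' representative
  vectors (two vectorization methods, averaged, /180°);
* γ_d — average displacement of equivalent swapped residues divided by the
  bounding-box diagonal of the two swapped domains;
* μ_sd — minimal structural diversity of the swapped domains (fragment RMSD
  over normalized fragment alignment size).

DS = η · S₀ · exp(−[m₀(1−γ_θ) + m₁(1−γ_d) + m₂·μ_sd]), clamped to [0, 1].
Common homologs score near zero (no hinge, tiny γ's); genuine swaps keep S₀.
The weights m₀..m₂ and the decision cutoff are trained by an exhaustive grid
search maximizing the Matthews correlation coefficient.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .config import Config, DEFAULT
from .structure_io import vectorize_segment, vector_angle

__all__ = [
    "DSFactors",
    "DSModel",
    "gamma_theta",
    "gamma_d",
    "mu_sd",
    "ds_score",
    "train_model",
    "classification_metrics",
]


@dataclass
class DSFactors:
    gamma_theta: float        # [0, 1]
    gamma_d: float | None     # [0, 1]; None when no equivalent swapped pairs exist
    mu_sd: float | None       # ≥ 0
    eta: int                  # {0, 1}
    s0: float                 # normalized similarity, the vQ-score


@dataclass
class DSModel:
    m0: float = 1.0
    m1: float = 1.0
    m2: float = 1.0
    cutoff: float = 0.25
    training_mcc: float | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DSModel":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d[k] for k in ("m0", "m1", "m2", "cutoff") if k in d},
                   training_mcc=d.get("training_mcc"))


# ---------------------------------------------------------------------------
# factors

def gamma_theta(coords_q: np.ndarray, coords_s: np.ndarray,
                o_q_ca: np.ndarray, o_s_ca: np.ndarray,
                hinge_at: str = "start") -> float:
    """Normalized angular difference of the swapped domains.

    ``coords_*`` are the swapped-domain Cα coordinates (hinge loop excluded)
    with the subject already under the main-domain transform.  Method 1 fits a
    least-squares line through each whole domain (N→C oriented); method 2
    points from the refined opening point to C₀, the geometric center of the
    central and the hinge-distal terminal residue.  γ_θ = (θ_x/180 + θ_y/180)/2.
    """
    thetas = []
    try:
        v1q, _, _ = vectorize_segment(coords_q)
        v1s, _, _ = vectorize_segment(coords_s)
        thetas.append(vector_angle(v1q, v1s))
    except ValueError:
        pass
    terminal = -1 if hinge_at == "start" else 0
    c0_q = 0.5 * (coords_q[len(coords_q) // 2] + coords_q[terminal])
    c0_s = 0.5 * (coords_s[len(coords_s) // 2] + coords_s[terminal])
    v2q = c0_q - o_q_ca
    v2s = c0_s - o_s_ca
    if np.linalg.norm(v2q) > 1e-9 and np.linalg.norm(v2s) > 1e-9:
        thetas.append(vector_angle(v2q, v2s))
    if not thetas:
        return 0.0
    return float(np.mean([t / 180.0 for t in thetas]))


def gamma_d(q_coords: np.ndarray, s_coords_moved: np.ndarray) -> float | None:
    """Average displacement of equivalent swapped residues over the diagonal
    of the axis-aligned bounding box of both domains' Cα coordinates.

    ``q_coords``/``s_coords_moved`` are the paired equivalent Cα positions
    with the subject under the main-domain transform.  None when no pairs.
    """
    if len(q_coords) == 0:
        return None
    d_avg = float(np.linalg.norm(q_coords - s_coords_moved, axis=1).mean())
    cloud = np.vstack([q_coords, s_coords_moved])
    d_max = float(np.linalg.norm(cloud.max(axis=0) - cloud.min(axis=0)))
    if d_max <= 0:
        return 0.0
    return min(d_avg / d_max, 1.0)


def mu_sd(rmsd_sd: float, n_e_sd: int, n_o_sd: int, n_c_sd: int) -> float | None:
    """Minimal structural diversity: RMSD over the normalized alignment size
    of the swapped domains.  Zero iff the domains superpose exactly."""
    if n_e_sd <= 0:
        return None
    return rmsd_sd / (n_e_sd / min(n_o_sd, n_c_sd))


# ---------------------------------------------------------------------------
# score

def _penalty(gt: float, gd: float, mu: float, m0: float, m1: float, m2: float):
    return np.exp(-(m0 * (1.0 - gt) + m1 * (1.0 - gd) + m2 * mu))


def ds_score(factors: DSFactors, model: DSModel | None = None) -> float:
    """DS = η·S₀·f_p clamped to [0, 1]; zero whenever η = 0, S₀ = 0 or the
    displacement factor is undefined."""
    model = model or DSModel()
    if factors.eta == 0 or factors.s0 <= 0:
        return 0.0
    if factors.gamma_d is None or factors.mu_sd is None:
        return 0.0
    fp = _penalty(factors.gamma_theta, factors.gamma_d, factors.mu_sd,
                  model.m0, model.m1, model.m2)
    return float(np.clip(factors.eta * factors.s0 * fp, 0.0, 1.0))


# ---------------------------------------------------------------------------
# training

def _mcc_from_counts(tp, fp, tn, fn):
    tp, fp, tn, fn = (np.asarray(x, dtype=float) for x in (tp, fp, tn, fn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    num = tp * tn - fp * fn
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return mcc


def train_model(factor_list: list[DSFactors], labels: list[int] | np.ndarray,
                config: Config = DEFAULT) -> DSModel:
    """Exhaustive grid search over (m₀, m₁, m₂) and the score cutoff,
    maximizing the MCC on the labeled pairs.

    Deterministic: the grid is scanned in ascending parameter order and ties
    keep the first (smallest-parameter) optimum.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("training needs at least one positive and one negative label")
    if len(factor_list) != len(labels):
        raise ValueError("factors and labels differ in length")

    eta = np.array([f.eta for f in factor_list], dtype=float)
    s0 = np.array([f.s0 for f in factor_list], dtype=float)
    gt = np.array([f.gamma_theta for f in factor_list], dtype=float)
    gd = np.array([0.0 if f.gamma_d is None else f.gamma_d for f in factor_list])
    mu = np.array([0.0 if f.mu_sd is None else f.mu_sd for f in factor_list])
    defined = np.array([f.gamma_d is not None and f.mu_sd is not None
                        for f in factor_list], dtype=float)
    base = eta * s0 * defined

    grid = np.arange(0.0, config.grid_max + 1e-9, config.grid_step)
    m0g, m1g, m2g = np.meshgrid(grid, grid, grid, indexing="ij")
    combos = np.column_stack([m0g.ravel(), m1g.ravel(), m2g.ravel()])
    # scores: (n_combos, n_pairs)
    pen = np.exp(-(combos[:, [0]] * (1.0 - gt)[None, :]
                   + combos[:, [1]] * (1.0 - gd)[None, :]
                   + combos[:, [2]] * mu[None, :]))
    scores = np.clip(base[None, :] * pen, 0.0, 1.0)

    c0, c1, step = config.cutoff_grid
    cutoffs = np.arange(c0, c1 + 1e-9, step)
    best = None
    for cut in cutoffs:
        pred = scores > cut
        tp = (pred & labels[None, :]).sum(axis=1)
        fp = (pred & ~labels[None, :]).sum(axis=1)
        fn = (~pred & labels[None, :]).sum(axis=1)
        tn = (~pred & ~labels[None, :]).sum(axis=1)
        mcc = _mcc_from_counts(tp, fp, tn, fn)
        k = int(np.argmax(mcc))
        if best is None or mcc[k] > best[0] + 1e-12:
            best = (float(mcc[k]), combos[k], float(cut))
    mcc_best, (m0, m1, m2), cut = best
    return DSModel(float(m0), float(m1), float(m2), cut, training_mcc=mcc_best)


def classification_metrics(predictions, labels) -> dict:
    """MCC, sensitivity and specificity from binary predictions.

    An undefined MCC denominator is reported as 0 with ``mcc_undefined`` set.
    """
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    tn = int((~pred & ~lab).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    undefined = denom == 0
    mcc = 0.0 if undefined else (tp * tn - fp * fn) / np.sqrt(denom)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {"mcc": float(mcc), "sensitivity": float(sens), "specificity": float(spec),
            "tp": tp, "fp": fp, "tn": tn, "fn": fn, "mcc_undefined": undefined}
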