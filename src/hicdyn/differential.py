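"""The bounded relative-ratio differential statistic and four-way call typing.

For a bin pair observed with Z-scores ``z0`` (control) and ``z1`` (treated),
define exponential interaction strengths ``E = exp(z)`` on observed cells and
``E = 0`` on unobserved cells (the Z = 0 sentinel).  The relative ratio is

    r = (E1 - E0) / ((E1 + E0) / 2)

which is bounded in [-2, 2] and maps a fold change ``k = E1/E0`` to
``r = 2(k - 1)/(k + 1)``: a 2-fold gain gives r = 0.67, 5-fold 1.33,
10-fold ~1.63, and a contact present in only one condition saturates at
+2 (treatment-specific gain) or -2 (loss).  Cells unobserved in both
conditions are fixed at r = 0 and excluded from analysis.

A *strong* differential interaction is a cell with |r| at the saturation
bound and the observed condition's Z-score above a cutoff (default > 1);
calls are typed gain/loss x intra/inter by the sign of r and whether the
two bins share a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedGenome
from .zscores import ZScoreMatrix

_EPS = 1e-12


def exp_strength(z, observed):
    """Exponential interaction strength: ``exp(z)`` if observed, else 0.

    The unobserved sentinel must map to strength 0 (not exp(0) = 1) for
    condition-exclusive contacts to saturate the relative ratio at +/-2.
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    out = np.where(observed, np.exp(z), 0.0)
    return out.item() if out.ndim == 0 else out


def relative_ratio(z0, obs0, z1, obs1):
    """Relative ratio r = (E1 - E0) / mean(E1, E0) in [-2, 2].

    Cells unobserved in both conditions return 0 (and are flagged excluded
    by :func:`relative_ratio_matrix`).  Accepts scalars or arrays.
    """
    e0 = np.asarray(exp_strength(z0, obs0), dtype=float)
    e1 = np.asarray(exp_strength(z1, obs1), dtype=float)
    denom = (e1 + e0) / 2.0
    r = np.zeros(np.broadcast(e0, e1).shape)
    np.divide(e1 - e0, denom, out=r, where=denom > 0)
    return r.item() if r.ndim == 0 else r


def fold_change_to_ratio(k):
    """Closed form r = 2(k - 1)/(k + 1) for fold change k > 0."""
    k = np.asarray(k, dtype=float)
    out = 2.0 * (k - 1.0) / (k + 1.0)
    return out.item() if out.ndim == 0 else out


def ratio_to_fold_change(r):
    """Inverse map k = (2 + r)/(2 - r) for |r| < 2."""
    r = np.asarray(r, dtype=float)
    out = (2.0 + r) / (2.0 - r)
    return out.item() if out.ndim == 0 else out


@dataclass
class RelativeRatioMatrix:
    """Cellwise relative ratios between two conditions of one genome."""

    genome: BinnedGenome
    r: np.ndarray  # (n, n) float in [-2, 2]
    excluded: np.ndarray  # (n, n) bool, True where unobserved in both


def relative_ratio_matrix(
    z0: ZScoreMatrix, z1: ZScoreMatrix
) -> RelativeRatioMatrix:
    """Relative ratio for every bin pair, treated (z1) minus control (z0)."""
    _check_same_genome(z0, z1)
    r = relative_ratio(z0.z, z0.mask, z1.z, z1.mask)
    return RelativeRatioMatrix(
        genome=z0.genome, r=r, excluded=~(z0.mask | z1.mask)
    )


@dataclass
class DifferentialCall:
    """One differential bin pair: gain/loss x intra/inter."""

    bin1: int
    bin2: int
    kind: str  # "gain" | "loss"
    span: str  # "intra" | "inter"
    ratio: float
    z0: float
    z1: float

    @property
    def call_type(self) -> str:
        return f"{self.kind}-{self.span}"


def classify_differential(
    z0: ZScoreMatrix,
    z1: ZScoreMatrix,
    ratio_cut: float = 2.0,
    z_cut: float = 1.0,
    mode: str = "strict",
) -> list[DifferentialCall]:
    """Call and type differential interactions between two conditions.

    strict mode (default)
        A cell is called iff |r| >= ``ratio_cut`` and the maximum Z-score
        over the conditions in which the cell is observed is strictly
        greater than ``z_cut``.  With the default ``ratio_cut = 2`` only
        condition-exclusive cells qualify, so the Z tested is that of the
        single observed condition.
    relaxed mode
        A cell is called iff |r| >= ``ratio_cut`` and the cell is observed
        in at least one condition; no Z cutoff is applied (observedness
        itself is the "Z-score is not zero" requirement, mediated by the
        mask so that an observed Z numerically equal to 0 still counts).

    Gains are treated-specific (r > 0, direction = treated minus control);
    each unordered pair is reported once, in genome order.
    """
    if not 0 < ratio_cut <= 2:
        raise ValueError("ratio_cut must be in (0, 2]")
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_same_genome(z0, z1)
    genome = z0.genome
    rr = relative_ratio_matrix(z0, z1)
    observed_any = ~rr.excluded
    zmax = np.maximum(
        np.where(z0.mask, z0.z, -np.inf), np.where(z1.mask, z1.z, -np.inf)
    )
    selected = observed_any & (np.abs(rr.r) >= ratio_cut - _EPS)
    if mode == "strict":
        selected &= zmax > z_cut
    selected &= np.triu(np.ones_like(selected, dtype=bool))  # one report per pair
    intra = genome.intra_mask()
    calls = []
    for i, j in np.argwhere(selected):
        i, j = int(i), int(j)
        calls.append(
            DifferentialCall(
                bin1=i,
                bin2=j,
                kind="gain" if rr.r[i, j] > 0 else "loss",
                span="intra" if intra[i, j] else "inter",
                ratio=float(rr.r[i, j]),
                z0=float(z0.z[i, j]),
                z1=float(z1.z[i, j]),
            )
        )
    return calls


def calls_to_frame(calls: list[DifferentialCall], genome: BinnedGenome) -> pd.DataFrame:
    """Tabulate calls with 1-based bin coordinates."""
    rows = []
    for c in calls:
        ch1, s1, e1 = genome.bin_location(c.bin1)
        ch2, s2, e2 = genome.bin_location(c.bin2)
        rows.append(
            {
                "chrom1": ch1, "start1": s1, "end1": e1,
                "chrom2": ch2, "start2": s2, "end2": e2,
                "type": c.call_type,
                "relative_ratio": round(c.ratio, 2),
                "z_control": c.z0, "z_treated": c.z1,
            }
        )
    columns = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "type", "relative_ratio", "z_control", "z_treated",
    ]
    return pd.DataFrame(rows, columns=columns)


def gain_loss_profile(
    calls: list[DifferentialCall], genome: BinnedGenome
) -> pd.DataFrame:
    """Per-bin counts of gained (positive) and lost (negative) interactions.

    Every call increments both endpoint bins (a within-bin call increments
    its bin once).  Losses are stored as negative values so the two columns
    plot directly as the paired positive/negative profile.
    """
    gains = np.zeros(genome.n_bins, dtype=np.int64)
    losses = np.zeros(genome.n_bins, dtype=np.int64)
    for c in calls:
        target = gains if c.kind == "gain" else losses
        target[c.bin1] += 1
        if c.bin2 != c.bin1:
            target[c.bin2] += 1
    locs = [genome.bin_location(i) for i in range(genome.n_bins)]
    return pd.DataFrame(
        {
            "chrom": [c for c, _, _ in locs],
            "start": [s for _, s, _ in locs],
            "end": [e for _, _, e in locs],
            "gains": gains,
            "losses": -losses,
        }
    )


def _check_same_genome(a: ZScoreMatrix, b: ZScoreMatrix) -> None:
    if a.genome.names != b.genome.names or a.genome.lengths != b.genome.lengths:
        raise ValueError("conditions use different genomes")
    if a.genome.window != b.genome.window:
        raise ValueError("conditions use different window sizes")
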