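"""Bliss-independence analysis of drug-combination checkerboards.

A checkerboard plates two drugs on crossed concentration grids (each
grid includes zero, so the first row and column carry the single-agent
responses).  With T/C as fraction unaffected, Bliss independence
predicts a combination effect

    E12 = E1 * E2         (Bliss neutral value)

from the measured single-agent effects on the same plate, and the
Bliss index

    BI = E12 - T/C[combination]

is positive when the combination inhibits more than expected (synergy)
and negative for antagonism.  Cells are flagged at |BI| >= 0.15 and the
assay-level call generalises the 3-of-25-conditions counting rule to a
fraction of the matrix size, so 5x5 and 8x2 layouts are classified by
the same logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TCMatrix",
    "BlissResult",
    "bliss_neutral",
    "bliss_index",
    "modeled_tc",
    "clip_for_display",
    "analyze_matrix",
    "classify_assay",
    "write_matrix_csv",
    "read_matrix_csv",
]

#: BI at or beyond this magnitude flags a cell (ties count as flagged).
DEFAULT_BI_THRESHOLD = 0.15
#: Fraction of combination cells that must be flagged before the
#: assay-level call escalates; ceil(0.12 * 25) = 3 recovers the
#: 3-of-25-conditions rule on a 5x5 checkerboard.
DEFAULT_FLAG_FRACTION = 0.12


def bliss_neutral(e1: float, e2: float) -> float:
    """Expected combination T/C under independence: ``e1 * e2``."""
    if e1 < 0 or e2 < 0:
        raise ValueError("fraction-unaffected inputs must be non-negative")
    return e1 * e2


def bliss_index(neutral: float, tc_combo: float) -> float:
    """Bliss index: expected minus observed combination T/C."""
    if neutral < 0 or tc_combo < 0:
        raise ValueError("T/C inputs must be non-negative")
    return neutral - tc_combo


def modeled_tc(replicates) -> float:
    """Modeled T/C: arithmetic mean of the measured replicate T/C values.

    The unclipped mean feeds the Bliss computation; use
    :func:`clip_for_display` for the heat-map copy.
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[~np.isnan(reps)]
    if reps.size == 0:
        raise ValueError("at least one replicate required")
    return float(reps.mean())


def clip_for_display(tc) -> np.ndarray | float:
    """Clip T/C to the [0, 1] heat-map display scale (computation stays unclipped)."""
    return np.clip(tc, 0.0, 1.0)


@dataclass
class TCMatrix:
    """T/C fractions on a drug-A x drug-B concentration grid.

    ``conc_a``/``conc_b`` are ascending molar grids, each starting at 0;
    ``replicates`` has shape (len(conc_a), len(conc_b), n_rep) with NaN
    for missing wells.  Row/column 0 hold the single-agent responses and
    cell (0, 0) is fixed at T/C = 1 by construction (untreated).
    """

    conc_a: np.ndarray
    conc_b: np.ndarray
    replicates: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.conc_a[0] != 0 or self.conc_b[0] != 0:
            raise ValueError("concentration grids must start at 0 (single-agent axis)")
        if np.any(np.diff(self.conc_a) <= 0) or np.any(np.diff(self.conc_b) <= 0):
            raise ValueError("concentration grids must be strictly ascending")
        if self.replicates.shape[:2] != (len(self.conc_a), len(self.conc_b)):
            raise ValueError("replicate grid shape does not match concentration grids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.replicates) < 0:
                raise ValueError("T/C values must be non-negative")
        self.replicates[0, 0, :] = np.nan
        self.replicates[0, 0, 0] = 1.0  # untreated control cell

    @property
    def modeled(self) -> np.ndarray:
        """Mean-over-replicates T/C grid (NaN where a cell has no data)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            return np.nanmean(self.replicates, axis=2)

    def transpose(self) -> "TCMatrix":
        return TCMatrix(
            conc_a=self.conc_b.copy(),
            conc_b=self.conc_a.copy(),
            replicates=np.swapaxes(self.replicates, 0, 1).copy(),
            meta=dict(self.meta),
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, assay_id: str | None = None,
                  meta: dict | None = None) -> "TCMatrix":
        """Build from a long table with columns conc_a, conc_b, tc (molar, T/C).

        Rows with conc_a == conc_b == 0 are the untreated reference and
        are pinned to T/C = 1.
        """
        if assay_id is not None:
            df = df[df["assay_id"] == assay_id]
        conc_a = np.sort(df["conc_a"].unique())
        conc_b = np.sort(df["conc_b"].unique())
        if conc_a[0] != 0 or conc_b[0] != 0:
            raise ValueError("long table must include single-agent rows (conc 0)")
        n_rep = int(df.groupby(["conc_a", "conc_b"]).size().max())
        reps = np.full((len(conc_a), len(conc_b), n_rep), np.nan)
        ia = {c: i for i, c in enumerate(conc_a)}
        ib = {c: i for i, c in enumerate(conc_b)}
        counters: dict[tuple[int, int], int] = {}
        for _, row in df.iterrows():
            i, j = ia[row["conc_a"]], ib[row["conc_b"]]
            k = counters.get((i, j), 0)
            reps[i, j, k] = row["tc"]
            counters[(i, j)] = k + 1
        return cls(conc_a=conc_a, conc_b=conc_b, replicates=reps, meta=meta or {})


@dataclass
class BlissResult:
    """Bliss grids, per-cell flags, flag counts and the assay-level call."""

    neutral: np.ndarray
    index: np.ndarray
    flags: np.ndarray  # object array of {"synergy","neutral","antagonism"} / None
    counts: dict
    call: str
    bi_threshold: float
    flag_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "call": self.call,
                "bi_threshold": self.bi_threshold,
                "flag_fraction": self.flag_fraction,
            },
            indent=2,
        )


def analyze_matrix(m: TCMatrix,
                   bi_threshold: float = DEFAULT_BI_THRESHOLD,
                   flag_fraction: float = DEFAULT_FLAG_FRACTION) -> BlissResult:
    """Fill Bliss neutral/index grids for every combination cell and classify.

    Replicates are averaged to the modeled T/C first; E1/E2 are the
    measured single-agent values from the same plate (row conc_b = 0 and
    column conc_a = 0), not fitted curves.  Combination cells with no
    surviving replicate are excluded from the counted total.
    """
    tc = m.modeled
    na, nb = tc.shape
    if np.isnan(tc[1:, 0]).any() or np.isnan(tc[0, 1:]).any():
        raise ValueError("missing single-agent row/column; cannot form Bliss expectation")
    neutral = np.full_like(tc, np.nan)
    index = np.full_like(tc, np.nan)
    flags = np.full((na, nb), None, dtype=object)
    n_syn = n_ant = n_neu = n_total = 0
    for i in range(1, na):
        for j in range(1, nb):
            if math.isnan(tc[i, j]):
                continue  # cell lost both replicates; excluded from n_total
            e12 = bliss_neutral(tc[i, 0], tc[0, j])
            bi = bliss_index(e12, tc[i, j])
            neutral[i, j] = e12
            index[i, j] = bi
            n_total += 1
            if bi >= bi_threshold:
                flags[i, j] = "synergy"
                n_syn += 1
            elif bi <= -bi_threshold:
                flags[i, j] = "antagonism"
                n_ant += 1
            else:
                flags[i, j] = "neutral"
                n_neu += 1
    counts = {
        "n_synergy": n_syn,
        "n_antagonism": n_ant,
        "n_neutral": n_neu,
        "n_total": n_total,
    }
    call = classify_assay(counts, flag_fraction=flag_fraction)
    return BlissResult(neutral=neutral, index=index, flags=flags, counts=counts,
                       call=call, bi_threshold=bi_threshold,
                       flag_fraction=flag_fraction)


def classify_assay(counts: dict, flag_fraction: float = DEFAULT_FLAG_FRACTION) -> str:
    """Assay-level call from per-cell flag counts.

    With k = ceil(flag_fraction * n_total): synergy if n_synergy > k,
    slight_synergy if n_synergy == k (antagonism symmetric), additive if
    n_neutral > n_total - k - 1; for a 25-cell checkerboard this is the
    >3/25, =3/25, >22/25 counting rule.  If synergy and antagonism fire
    together the call is ``mixed``.
    """
    n_total = counts["n_total"]
    if n_total == 0:
        raise ValueError("no combination cells to classify")
    n_syn, n_ant, n_neu = counts["n_synergy"], counts["n_antagonism"], counts["n_neutral"]
    if n_syn + n_ant + n_neu != n_total:
        raise ValueError("flag counts do not sum to n_total")
    k = math.ceil(flag_fraction * n_total)
    syn_fire, ant_fire = n_syn > k, n_ant > k
    if syn_fire and ant_fire:
        return "mixed"
    if syn_fire:
        return "synergy"
    if ant_fire:
        return "antagonism"
    if n_syn == k and n_ant == k:
        return "mixed"
    if n_syn == k:
        return "slight_synergy"
    if n_ant == k:
        return "slight_antagonism"
    return "additive"


def write_matrix_csv(path, grid: np.ndarray, conc_a, conc_b) -> None:
    """Write a numeric grid with concentration header row/column.

    Floats are written with shortest round-trip repr so a
    write -> read -> analyze cycle reproduces the grid bitwise.
    """
    df = pd.DataFrame(grid, index=np.asarray(conc_a, dtype=float),
                      columns=np.asarray(conc_b, dtype=float))
    df.index.name = "conc_a\\conc_b"
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_matrix_csv`: (grid, conc_a, conc_b)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    conc_a = df.index.to_numpy(dtype=float)
    conc_b = df.columns.to_numpy(dtype=float)
    return df.to_numpy(dtype=float), conc_a, conc_b


def plot_heatmap(result: BlissResult, m: TCMatrix, path) -> None:
    """Blue/white/red Bliss-index heat map (synergy >= +0.15 blue,
    antagonism <= -0.15 red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    grid = result.index[1:, 1:]
    im = ax.imshow(grid, cmap="RdBu", vmin=-1, vmax=1, origin="lower")
    ax.set_xticks(range(grid.shape[1]),
                  [f"{c:.3g}" for c in m.conc_b[1:]], rotation=45)
    ax.set_yticks(range(grid.shape[0]), [f"{c:.3g}" for c in m.conc_a[1:]])
    ax.set_xlabel(m.meta.get("drug_b", "drug B") + " [M]")
    ax.set_ylabel(m.meta.get("drug_a", "drug A") + " [M]")
    ax.set_title(f"Bliss index ({result.call})")
    fig.colorbar(im, ax=ax, label="Bliss index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
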