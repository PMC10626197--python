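"""Bliss synergy scoring from dose-response matrices.

The Bliss independence model posits that, absent interaction, the viability
under a combination equals the product of single-agent viabilities,
``V(c1, c2) = V(c1) V(c2)``.  Writing inhibition ``I = 1 - V``, the excess
over independence at a dose pair is

    s(c1, c2) = I(c1, c2) - I(c1) - I(c2) + I(c1) I(c2),

and a block-level synergy label is obtained by pooling the excess over the
dose grid (max by default; the maximum is far less sensitive to the tested
concentration window than the mean).  Scores are reported on the x100
percentage scale; all internal arithmetic is in fractional units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseBlock",
    "SynergyRecord",
    "NoiseEstimate",
    "Pooling",
    "bliss_excess_matrix",
    "pool_synergy",
    "block_synergy",
    "normalize_viability_plate",
    "qc_filter_blocks",
    "estimate_replicate_noise",
    "read_blocks_csv",
    "write_blocks_csv",
    "read_synergy_csv",
    "write_synergy_csv",
]


class Pooling(str, Enum):
    max = "max"
    mean = "mean"


@dataclass
class DoseResponseBlock:
    """One drug pair x cell line inhibition matrix with replicates.

    ``inhibition`` has shape (n_rep, len(conc_a), len(conc_b)) with values in
    [0, 1] after normalisation.  Concentrations are ascending; a leading 0
    entry marks the single-agent / control margins: row ``I[:, i, 0]`` is the
    single-agent response of drug_a and column ``I[:, 0, j]`` that of drug_b,
    with ``I[:, 0, 0] = 0`` under exact normalisation.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self):
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.ndim == 2:
            self.inhibition = self.inhibition[None]
        if np.any(np.diff(self.conc_a) <= 0) or np.any(np.diff(self.conc_b) <= 0):
            raise ValueError("concentration lists must be strictly increasing")
        if self.inhibition.shape[1:] != (len(self.conc_a), len(self.conc_b)):
            raise ValueError(
                f"inhibition shape {self.inhibition.shape} does not match the "
                f"{len(self.conc_a)}x{len(self.conc_b)} dose grid"
            )

    @property
    def n_replicates(self) -> int:
        return self.inhibition.shape[0]


@dataclass
class SynergyRecord:
    """Pooled synergy label for one (drug pair, cell line) combination.

    Drug pair is stored in canonical sorted order; ``synergy`` is on the x100
    percentage scale.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    synergy: float
    pooling: str = "max"
    study: str = ""

    def __post_init__(self):
        if self.drug_b < self.drug_a:
            self.drug_a, self.drug_b = self.drug_b, self.drug_a
        if not np.isfinite(self.synergy):
            raise ValueError("synergy must be finite")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)

    @property
    def triplet(self) -> tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.cell_line)


@dataclass
class NoiseEstimate:
    """Mean per-triplet replicate standard deviation of pooled synergy."""

    eta_bar: float
    n_triplets: int
    per_triplet: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eta_bar < 0 or self.n_triplets < 1:
            raise ValueError("invalid noise estimate")


def _single_agent_margins(block: DoseResponseBlock, inh: np.ndarray):
    """Extract single-agent inhibition vectors over nonzero doses."""
    za = int(block.conc_a[0] == 0)
    zb = int(block.conc_b[0] == 0)
    if za == 0:
        raise ValueError(
            f"missing zero-dose column for single-agent response of {block.drug_b}"
        )
    if zb == 0:
        raise ValueError(
            f"missing zero-dose row for single-agent response of {block.drug_a}"
        )
    i1 = inh[za:, 0]       # drug_a alone, nonzero doses
    i2 = inh[0, zb:]       # drug_b alone, nonzero doses
    i12 = inh[za:, zb:]
    return i1, i2, i12


def bliss_excess_matrix(
    block: DoseResponseBlock, aggregate_replicates: str = "before"
) -> np.ndarray:
    """Elementwise Bliss excess over the nonzero-dose grid, on the x100 scale.

    ``aggregate_replicates='before'`` averages replicate inhibition first and
    scores once; ``'after'`` scores each replicate and averages the excess
    matrices.  Zero-dose margins are used as the single-agent responses and
    are excluded from the output.
    """
    inh = block.inhibition
    if np.isnan(inh).any():
        bad = np.argwhere(np.isnan(inh))
        raise ValueError(f"NaN inhibition at (replicate, row, col) indices {bad.tolist()[:10]}")
    if aggregate_replicates not in ("before", "after"):
        raise ValueError(f"unknown replicate aggregation '{aggregate_replicates}'")

    def _excess(one_rep: np.ndarray) -> np.ndarray:
        i1, i2, i12 = _single_agent_margins(block, one_rep)
        return i12 - i1[:, None] - i2[None, :] + i1[:, None] * i2[None, :]

    if aggregate_replicates == "before":
        excess = _excess(inh.mean(axis=0))
    else:
        excess = np.mean([_excess(inh[r]) for r in range(inh.shape[0])], axis=0)
    return excess * 100.0


def pool_synergy(excess: np.ndarray, pooling: str | Pooling = Pooling.max) -> float:
    """Pool an excess matrix to a single synergy score (max or mean)."""
    excess = np.asarray(excess, dtype=float)
    if excess.size == 0:
        raise ValueError("cannot pool an empty Bliss excess matrix")
    pooling = Pooling(pooling)
    if pooling is Pooling.max:
        return float(excess.max())
    return float(excess.mean())


def block_synergy(
    block: DoseResponseBlock,
    pooling: str | Pooling = Pooling.max,
    aggregate_replicates: str = "before",
    study: str = "",
) -> SynergyRecord:
    """Score one block end to end: Bliss excess then pooling."""
    excess = bliss_excess_matrix(block, aggregate_replicates)
    return SynergyRecord(
        block.drug_a, block.drug_b, block.cell_line,
        pool_synergy(excess, pooling), pooling=Pooling(pooling).value, study=study,
    )


def normalize_viability_plate(
    raw_viability: np.ndarray,
    dox_anchor: np.ndarray | float,
    dmso_anchor: np.ndarray | float | None = None,
    *,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
    cell_line: str = "",
    conc_a: np.ndarray | None = None,
    conc_b: np.ndarray | None = None,
) -> DoseResponseBlock:
    """Anchor raw viability to controls and convert to fractional inhibition.

    0% viability is anchored at the highest-concentration doxorubicin well
    per replicate (total-kill positive control); 100% at the (0, 0) DMSO
    control per combination.  Values are capped and linearly scaled to
    [0, 100] and returned as inhibition ``I = 1 - V/100``.

    ``raw_viability`` has shape (n_rep, n_a, n_b) (or (n_a, n_b) for a single
    replicate) including the zero-dose margins at index 0.  ``dox_anchor`` is
    a scalar or per-replicate vector; ``dmso_anchor`` defaults to the mean of
    the (0, 0) wells across replicates.
    """
    raw = np.asarray(raw_viability, dtype=float)
    if raw.ndim == 2:
        raw = raw[None]
    n_rep = raw.shape[0]
    if dox_anchor is None:
        raise ValueError("missing control: doxorubicin total-kill anchor")
    dox = np.broadcast_to(np.asarray(dox_anchor, dtype=float), (n_rep,)).astype(float)
    if dmso_anchor is None:
        dmso_anchor = float(raw[:, 0, 0].mean())
    dmso = float(dmso_anchor)
    if not np.isfinite(dmso):
        raise ValueError("missing control: DMSO (0,0) anchor")
    span = dmso - dox
    if np.any(span <= 0):
        raise ValueError("DMSO anchor must exceed the doxorubicin anchor")
    scaled = (raw - dox[:, None, None]) / span[:, None, None] * 100.0
    scaled = np.clip(scaled, 0.0, 100.0)
    inhibition = 1.0 - scaled / 100.0
    na, nb = raw.shape[1], raw.shape[2]
    if conc_a is None:
        conc_a = np.arange(na, dtype=float)
    if conc_b is None:
        conc_b = np.arange(nb, dtype=float)
    return DoseResponseBlock(drug_a, drug_b, cell_line, conc_a, conc_b, inhibition)


_QC_STD_MIN = 0.05       # rule (a): inhibition std must exceed this
_QC_MIN_DIM = 3          # rule (b): at least 3x3 dose grid
_QC_MEAN_LO = 0.05       # rule (c): mean inhibition strictly inside (0.05, 0.95)
_QC_MEAN_HI = 0.95


def qc_filter_blocks(
    blocks: list[DoseResponseBlock],
) -> tuple[list[DoseResponseBlock], dict[str, int]]:
    """Quality-control filter over dose-response blocks.

    Rejects (a) near-constant blocks (inhibition standard deviation <= 0.05),
    (b) blocks smaller than 3x3, (c) blocks with extreme mean inhibition
    (outside the open interval (0.05, 0.95)).  Returns the retained blocks
    and a rejection report keyed by rule.  Idempotent by construction.
    """
    retained: list[DoseResponseBlock] = []
    report = {"a": 0, "b": 0, "c": 0, "retained": 0}
    for block in blocks:
        inh = block.inhibition
        if inh.std() <= _QC_STD_MIN:
            report["a"] += 1
            continue
        if len(block.conc_a) < _QC_MIN_DIM or len(block.conc_b) < _QC_MIN_DIM:
            report["b"] += 1
            continue
        mean = inh.mean()
        if not (_QC_MEAN_LO < mean < _QC_MEAN_HI):
            report["c"] += 1
            continue
        retained.append(block)
    report["retained"] = len(retained)
    return retained, report


def estimate_replicate_noise(records: list[SynergyRecord]) -> NoiseEstimate:
    """Average replicate noise of the pooled synergy score.

    Groups records by (drug_a, drug_b, cell_line), computes the sample
    (n-1) standard deviation of the synergy within each replicated triplet,
    and averages across triplets.
    """
    groups: dict[tuple, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.triplet, []).append(rec.synergy)
    per_triplet = {
        trip: float(np.std(vals, ddof=1))
        for trip, vals in groups.items()
        if len(vals) >= 2
    }
    if not per_triplet:
        raise ValueError("no replicated (drug_a, drug_b, cell_line) triplet found")
    eta_bar = float(np.mean(list(per_triplet.values())))
    return NoiseEstimate(eta_bar=eta_bar, n_triplets=len(per_triplet),
                         per_triplet=per_triplet)


# ---------------------------------------------------------------------------
# Long-format CSV interchange
# ---------------------------------------------------------------------------

_BLOCK_COLS = ["drug_a", "drug_b", "cell_line", "conc_a", "conc_b", "replicate", "inhibition"]


def write_blocks_csv(blocks: list[DoseResponseBlock], path) -> None:
    rows = []
    for bl in blocks:
        for r in range(bl.n_replicates):
            for i, ca in enumerate(bl.conc_a):
                for j, cb in enumerate(bl.conc_b):
                    rows.append((bl.drug_a, bl.drug_b, bl.cell_line, ca, cb, r,
                                 bl.inhibition[r, i, j]))
    pd.DataFrame(rows, columns=_BLOCK_COLS).to_csv(path, index=False)


def read_blocks_csv(path) -> list[DoseResponseBlock]:
    df = pd.read_csv(path)
    missing = set(_BLOCK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"block CSV missing columns {sorted(missing)}")
    blocks = []
    for (da, db, cl), grp in df.groupby(["drug_a", "drug_b", "cell_line"], sort=False):
        conc_a = np.sort(grp["conc_a"].unique())
        conc_b = np.sort(grp["conc_b"].unique())
        reps = np.sort(grp["replicate"].unique())
        inh = np.full((len(reps), len(conc_a), len(conc_b)), np.nan)
        ia = {c: i for i, c in enumerate(conc_a)}
        ib = {c: i for i, c in enumerate(conc_b)}
        ir = {r: i for i, r in enumerate(reps)}
        for row in grp.itertuples(index=False):
            inh[ir[row.replicate], ia[row.conc_a], ib[row.conc_b]] = row.inhibition
        blocks.append(DoseResponseBlock(str(da), str(db), str(cl), conc_a, conc_b, inh))
    return blocks


def write_synergy_csv(records: list[SynergyRecord], path) -> None:
    pd.DataFrame(
        [(r.drug_a, r.drug_b, r.cell_line, r.synergy, r.pooling, r.study) for r in records],
        columns=["drug_a", "drug_b", "cell_line", "synergy", "pooling", "study"],
    ).to_csv(path, index=False)


def read_synergy_csv(path) -> list[SynergyRecord]:
    df = pd.read_csv(path)
    for col, default in (("cell_line", ""), ("pooling", "max"), ("study", "")):
        if col not in df.columns:
            df[col] = default
    return [
        SynergyRecord(str(r.drug_a), str(r.drug_b), str(r.cell_line), float(r.synergy),
                      pooling=str(r.pooling), study=str(r.study))
        for r in df.itertuples(index=False)
    ]
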