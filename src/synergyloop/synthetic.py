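"""Synthetic drug libraries, synergy landscapes and dose-response blocks.

The generator emulates the statistical structure the pipeline assumes in
real combination screens: drugs carry latent mechanisms of action whose
fingerprint signatures make structurally similar drugs mechanistically
similar; synergy is a property of mechanism pairs, so the landscape over
drug pairs is heavy-tailed -- most scores scatter near zero with a small
planted fraction of large positives; observations are the true scores plus
Gaussian replicate noise of level eta; and each pair can be expanded into a
6x6 dose-response block whose max-pooled Bliss score recovers the planted
synergy exactly when noise is off.

All randomness flows from a single study seed through named substreams
(library, landscape, noise, doses), so every artifact regenerates
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseBlock, SynergyRecord
from .featurization import DrugRecord

__all__ = [
    "LandscapeParams",
    "SyntheticDrug",
    "SyntheticStudy",
    "generate_drug_library",
    "generate_synergy_landscape",
    "generate_observations",
    "generate_dose_response_blocks",
    "generate_study",
]


@dataclass
class LandscapeParams:
    """Study conditions for the synthetic generator.

    ``synergy_lookup`` maps a sorted mechanism pair to its planted effect
    size (x100 Bliss scale); when empty it is populated by
    :func:`generate_synergy_landscape` with ``n_planted_mech_pairs`` pairs
    whose effects follow a location-scale exponential tail
    (35 + Exp(10), truncated at 62 -- the upper edge of what a 6x6 block
    with the generator's single-agent envelope can represent clip-free).
    ``background_sd`` spreads non-planted pair scores around zero; ``eta``
    is the observation-noise standard deviation on the x100 synergy scale.
    """

    n_drugs: int = 60
    n_mechanisms: int = 10
    n_bits: int = 128
    flip_prob: float = 0.10
    n_planted_mech_pairs: int = 4
    effect_loc: float = 35.0
    effect_scale: float = 10.0
    effect_max: float = 62.0
    background_sd: float = 5.0
    background_clip: float = 15.0
    eta: float = 5.0
    seed: int = 0
    synergy_lookup: dict = field(default_factory=dict)
    mechanisms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.n_mechanisms > self.n_drugs:
            raise ValueError("cannot have more mechanisms than drugs")

def _stream(params: LandscapeParams, name: str) -> np.random.Generator:
    names = {"library": 1, "landscape": 2, "noise": 3, "doses": 4}
    return np.random.default_rng([params.seed, names[name]])


@dataclass
class SyntheticDrug(DrugRecord):
    """Library entry with its latent mechanism of action."""

    mechanism: int = 0


@dataclass
class SyntheticStudy:
    library: list[SyntheticDrug]
    true_table: pd.DataFrame
    observed_table: pd.DataFrame
    params: LandscapeParams
    blocks: list[DoseResponseBlock] | None = None

    def true_records(self, cell_line: str = "SYN") -> list[SynergyRecord]:
        return [SynergyRecord(r.drug_a, r.drug_b, cell_line, float(r.synergy))
                for r in self.true_table.itertuples(index=False)]

    def observed_records(self, cell_line: str = "SYN") -> list[SynergyRecord]:
        return [SynergyRecord(r.drug_a, r.drug_b, cell_line, float(r.synergy))
                for r in self.observed_table.itertuples(index=False)]

    def oracle(self) -> dict:
        """Pair -> observed synergy lookup for SMO simulation."""
        return {tuple(sorted((r.drug_a, r.drug_b))): float(r.synergy)
                for r in self.observed_table.itertuples(index=False)}

    def pool(self) -> list[tuple[str, str]]:
        return [tuple(sorted((r.drug_a, r.drug_b)))
                for r in self.true_table.itertuples(index=False)]


def generate_drug_library(params: LandscapeParams) -> list[SyntheticDrug]:
    """Drugs with mechanism assignments and mechanism-correlated
    pseudo-fingerprints.

    Each mechanism gets a deterministic signature bit pattern; a drug's
    pseudo-fingerprint is its mechanism signature with independent seeded
    bit flips at ``flip_prob``, so within-mechanism Tanimoto similarity
    exceeds the cross-mechanism level -- the structure/mechanism correlation
    real fingerprints carry.
    """
    if params.n_drugs < 2:
        raise ValueError("need at least two drugs")
    rng = _stream(params, "library")
    signatures = rng.random((params.n_mechanisms, params.n_bits)) < 0.5
    mech = np.resize(np.arange(params.n_mechanisms), params.n_drugs)
    rng.shuffle(mech)
    library = []
    width = len(str(params.n_drugs - 1))
    for i in range(params.n_drugs):
        flips = rng.random(params.n_bits) < params.flip_prob
        fp = np.logical_xor(signatures[mech[i]], flips).astype(np.uint8)
        drug = SyntheticDrug(drug_id=f"SYN-{i:0{width}d}", smiles=None,
                             fingerprint=fp, mechanism=int(mech[i]))
        library.append(drug)
        params.mechanisms[drug.drug_id] = int(mech[i])
    return library


def generate_synergy_landscape(
    library: list[SyntheticDrug], params: LandscapeParams
) -> pd.DataFrame:
    """True synergy over all drug pairs (symmetric; canonical pair order).

    Pairs whose sorted mechanism pair is in ``synergy_lookup`` take the
    planted effect; every other pair draws from N(0, background_sd).  With a
    non-empty lookup the score distribution is heavy-tailed (positive excess
    kurtosis).
    """
    if not library:
        raise ValueError("empty library")
    rng = _stream(params, "landscape")
    if not params.synergy_lookup and params.n_planted_mech_pairs > 0:
        cross = [(a, b) for a in range(params.n_mechanisms)
                 for b in range(a + 1, params.n_mechanisms)]
        picks = rng.choice(len(cross), size=min(params.n_planted_mech_pairs, len(cross)),
                           replace=False)
        for p in picks:
            effect = params.effect_loc + rng.exponential(params.effect_scale)
            params.synergy_lookup[cross[int(p)]] = float(min(effect, params.effect_max))
    rows = []
    for i in range(len(library)):
        for j in range(i + 1, len(library)):
            a, b = library[i], library[j]
            mpair = tuple(sorted((a.mechanism, b.mechanism)))
            if mpair in params.synergy_lookup:
                s = params.synergy_lookup[mpair]
            else:
                # background clipped to the range a max-pooled Bliss surface
                # can actually express (strong antagonism is invisible to the
                # max over a grid that includes near-inert dose pairs)
                s = float(np.clip(rng.normal(0.0, params.background_sd),
                                  -params.background_clip,
                                  params.background_clip))
            da, db = sorted((a.drug_id, b.drug_id))
            rows.append((da, db, float(s)))
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "synergy"])


def generate_observations(
    true_table: pd.DataFrame, eta, seed: int
) -> pd.DataFrame:
    """Observed = true + iid N(0, eta^2); ``eta`` may be a scalar or a
    per-pair array (heteroscedastic variant).  eta = 0 reproduces the true
    table exactly."""
    eta_arr = np.broadcast_to(np.asarray(eta, dtype=float), (len(true_table),))
    if np.any(eta_arr < 0):
        raise ValueError("eta must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=len(true_table)) * eta_arr
    out = true_table.copy()
    out["synergy"] = true_table["synergy"].to_numpy() + noise
    return out


def _single_agent_curve(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    """Four-parameter sigmoid over the nonzero doses: baseline inhibition
    I_lo in [0.08, 0.2], top-dose asymptote I_hi in [0.55, 0.9], potency
    log-uniform over the grid span, Hill slope in [0.5, 2]."""
    i_lo = rng.uniform(0.08, 0.20)
    i_hi = rng.uniform(0.55, 0.90)
    ec50 = np.exp(rng.uniform(np.log(conc[0]), np.log(conc[-1])))
    h = rng.uniform(0.5, 2.0)
    frac = conc ** h / (conc ** h + ec50 ** h)
    return i_lo + (i_hi - i_lo) * frac


def generate_dose_response_blocks(
    library: list[SyntheticDrug],
    true_table: pd.DataFrame,
    params: LandscapeParams,
    grid: int = 6,
    n_replicates: int = 3,
    pairs: list[tuple[str, str]] | None = None,
) -> list[DoseResponseBlock]:
    """Expand pairs into dose-response blocks that round-trip through Bliss
    scoring.

    The grid is a zero dose plus ``grid - 1`` concentrations in a 1:3
    dilution series.  The combination surface is the Bliss-independence
    surface of two single-agent sigmoids plus an excess field scaled so the
    noiseless max-pooled Bliss score equals the pair's true synergy: a
    localized Gaussian bump (seeded center with inhibition headroom) for
    positive scores, a uniform offset for non-positive ones (a localized
    negative bump would be invisible to max pooling).  Curve parameters are
    drawn per block and resampled until the planted effect fits inside the
    surface's achievable Bliss-excess range, mirroring how assay dose ranges
    are re-titrated per experiment.  Replicate noise is Gaussian with sd
    ``params.eta / 100`` on the inhibition scale.
    """
    if grid < 2:
        raise ValueError("dose grid must be at least 2x2")
    rng = _stream(params, "doses")
    noise_rng = _stream(params, "noise")
    want = None if pairs is None else {tuple(sorted(p)) for p in pairs}
    lookup = {tuple(sorted((r.drug_a, r.drug_b))): float(r.synergy)
              for r in true_table.itertuples(index=False)}

    def draw_curves():
        out = []
        for _ in range(2):
            c_max = float(np.exp(rng.uniform(np.log(1.0), np.log(10.0))))
            conc = c_max * 3.0 ** (-np.arange(grid - 1)[::-1].astype(float))
            out.append((conc, _single_agent_curve(rng, conc)))
        return out

    blocks = []
    for (da, db), s100 in lookup.items():
        if want is not None and (da, db) not in want:
            continue
        s = s100 / 100.0
        best = None
        for _ in range(60):
            (ca, ia), (cb, ib) = draw_curves()
            indep = ia[:, None] + ib[None, :] - ia[:, None] * ib[None, :]
            lo = float(indep.min())
            headroom = (0.995 - lo - s) if s > 0 else (lo + s - 0.005)
            if best is None or headroom > best[0]:
                best = (headroom, ca, ia, cb, ib, indep)
            if headroom >= 0:
                break
        _, ca, ia, cb, ib, indep = best
        excess = np.zeros_like(indep)
        if s > 0:
            eligible = np.argwhere(indep + s <= 0.995)
            if len(eligible) == 0:  # outside the envelope: best-effort cell
                ci, cj = np.unravel_index(int(np.argmin(indep)), indep.shape)
                s_eff = 0.995 - indep[ci, cj]
            else:
                interior = [e for e in eligible
                            if 0 < e[0] < grid - 2 and 0 < e[1] < grid - 2]
                pick = interior if interior else list(eligible)
                ci, cj = pick[int(rng.integers(len(pick)))]
                s_eff = s
            ii, jj = np.meshgrid(np.arange(grid - 1), np.arange(grid - 1),
                                 indexing="ij")
            excess = s_eff * np.exp(-(((ii - ci) ** 2 + (jj - cj) ** 2) / 2.0))
        elif s < 0:
            s_eff = max(s, -float(indep.min()) + 1e-6)
            excess = np.full_like(indep, s_eff)
        surf = np.clip(indep + excess, 0.0, 1.0)

        full = np.zeros((grid, grid))
        full[1:, 0] = ia
        full[0, 1:] = ib
        full[1:, 1:] = surf
        reps = np.repeat(full[None], n_replicates, axis=0)
        if params.eta > 0:
            noise = noise_rng.normal(0.0, params.eta / 100.0, size=reps.shape)
            reps = np.clip(reps + noise, 0.0, 1.0)
        blocks.append(DoseResponseBlock(
            da, db, "SYN",
            conc_a=np.concatenate([[0.0], ca]),
            conc_b=np.concatenate([[0.0], cb]),
            inhibition=reps,
        ))
    return blocks


def generate_study(
    params: LandscapeParams, with_blocks: bool = False, grid: int = 6
) -> SyntheticStudy:
    """Generate library, true landscape and noisy observations in one call."""
    library = generate_drug_library(params)
    true_table = generate_synergy_landscape(library, params)
    observed = generate_observations(true_table, params.eta,
                                     seed=int(_stream(params, "noise").integers(2 ** 31)))
    blocks = None
    if with_blocks:
        blocks = generate_dose_response_blocks(library, true_table, params, grid=grid)
    return SyntheticStudy(library, true_table, observed, params, blocks)
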