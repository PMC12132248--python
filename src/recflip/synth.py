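"""Synthetic plate-reader datasets generated from the circuit model.

Emulates the structure of bulk fluorescence induction experiments: an
L-arabinose dose ladder, a small number of biological replicates per dose,
and arbitrary-unit GFP/RFP reads with multiplicative (lognormal) noise plus
an optional additive background.  Every downstream stage — normalization,
coupling-index computation, parameter fitting — can therefore be exercised
end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CircuitParameters, CircuitTopology
from .steady_state import DoseResponseTable, dose_response_scan

__all__ = [
    "DOSE_LADDER",
    "default_dose_ladder",
    "NoiseModel",
    "SyntheticPlateDataset",
    "generate_dataset",
]

#: The standard induction ladder in % w/v L-arabinose.
DOSE_LADDER = (0.0, 1.25e-4, 2.5e-4, 6.25e-4, 2.5e-3, 5e-3)

#: Extended 7-dose ladder: working solutions of 8.3%, 5%, 2.5%, 0.625%,
#: 0.25%, 0.125% and 0% diluted 1000-fold into the culture medium.
DOSE_LADDER_EXTENDED = DOSE_LADDER + (8.3e-3,)


def default_dose_ladder(extended: bool = False) -> np.ndarray:
    """The induction dose ladder (% w/v), ascending; 6 doses, or 7 if extended."""
    return np.array(DOSE_LADDER_EXTENDED if extended else DOSE_LADDER)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for simulated plate reads.

    ``cv_mult`` is the coefficient of variation of a lognormal multiplicative
    factor with mean exactly 1; ``bg_mean``/``bg_sd`` describe an additive
    Gaussian background in fluorescence a.u.  Generated reads are clipped at
    zero.  Fully reproducible from ``seed``.
    """

    cv_mult: float = 0.10
    bg_mean: float = 0.0
    bg_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_mult < 0 or self.bg_sd < 0:
            raise ValueError("cv_mult and bg_sd must be >= 0")


@dataclass
class SyntheticPlateDataset:
    """Simulated replicate fluorescence measurements plus their provenance.

    ``data`` has one row per (dose, replicate) with columns ``dose_pct``,
    ``replicate``, ``gfp_au``, ``rfp_au``.  The noiseless generating table
    is kept in ``reference`` for oracle comparisons.
    """

    data: pd.DataFrame
    n_reps: int
    topology: CircuitTopology
    true_params_digest: str
    noise: NoiseModel
    reference: DoseResponseTable | None = None

    def __post_init__(self) -> None:
        n_doses = self.data["dose_pct"].nunique()
        if len(self.data) != n_doses * self.n_reps:
            raise ValueError("row count must equal n_doses * n_reps")
        if (self.data[["gfp_au", "rfp_au"]].to_numpy() < 0).any():
            raise ValueError("fluorescence reads must be >= 0")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose_pct"].unique())

    def replicate_means(self) -> pd.DataFrame:
        """Per-dose replicate-mean GFP and RFP, sorted by dose."""
        return (
            self.data.groupby("dose_pct", as_index=False)[["gfp_au", "rfp_au"]]
            .mean()
            .sort_values("dose_pct", ignore_index=True)
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors with mean exactly 1 and CV ``cv``."""
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def generate_dataset(
    params: CircuitParameters,
    topology: CircuitTopology,
    doses=None,
    n_reps: int = 3,
    noise: NoiseModel | None = None,
    **ss_kwargs,
) -> SyntheticPlateDataset:
    """Simulate a replicate plate-reader dose-response experiment.

    For each dose the model steady state is computed, then each replicate
    draws ``max(0, S * (1 + eps_mult) + background)`` independently per
    channel.  With ``cv_mult = bg_mean = bg_sd = 0`` every read equals the
    steady state exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if doses is None:
        doses = default_dose_ladder()
    if noise is None:
        noise = NoiseModel()
    doses = np.asarray(doses, dtype=float)

    table = dose_response_scan(params, topology, doses, **ss_kwargs)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for i, dose in enumerate(doses):
        for rep in range(1, n_reps + 1):
            fg, fr = _lognormal_factors(rng, noise.cv_mult, 2)
            bg_g, bg_r = rng.normal(noise.bg_mean, noise.bg_sd, 2)
            rows.append(
                {
                    "dose_pct": dose,
                    "replicate": rep,
                    "gfp_au": max(0.0, table.G_ss[i] * fg + bg_g),
                    "rfp_au": max(0.0, table.R_ss[i] * fr + bg_r),
                }
            )
    return SyntheticPlateDataset(
        data=pd.DataFrame(rows),
        n_reps=n_reps,
        topology=topology,
        true_params_digest=params.digest,
        noise=noise,
        reference=table,
    )
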