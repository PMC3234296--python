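"""Synthetic qPCR study generator.

Emulates the structure of a multi-species efficiency study: 90 primer-pair
/ amplicon combinations with amplicons of 74-907 bp and primers of
18-25 nt, each combination run as many replicate reactions, with measured
efficiencies in [1, 2] scattered around a smooth ground-truth surface of
the six model covariates.  Defaults reproduce the study conditions the
model was designed for: residual noise SD sqrt(0.0092293) (the reported
scale estimate), a signal SD sized so the true signal-to-total variance
ratio is 0.41 (the reported adjusted R-squared), intercept 1.738, and
about 3,960 reactions in total.

Covariates are not resampled independently: sequences are drawn and the
features computed with :mod:`ampeff.seqfeatures`, so covariate
correlations are as realistic as random sequences allow.  What the
generator deliberately does not emulate: species/operator batch effects
(covariation artifacts in the original data) and primer-template
annealing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import QUANT_U, AmplificationCurve, logistic
from .errors import ConfigurationError
from .seqfeatures import FEATURE_COLUMNS, PrimerPair, extract_features

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "simulate_curve",
    "true_surface",
]

#: Residual noise SD matching the reported residual-variance scale estimate.
DEFAULT_NOISE_SD = math.sqrt(0.0092293)
#: Signal SD such that signal_var / (signal_var + noise_var) = 0.41.
DEFAULT_SIGNAL_SD = DEFAULT_NOISE_SD * math.sqrt(0.41 / 0.59)
DEFAULT_INTERCEPT = 1.738

_MACHINES = ["rotor-gene-2000", "mx3000p"]
_TEMPLATES = ["gDNA", "cDNA", "plasmid"]
_SOURCES = ["leaf", "root", "culture", "cytology"]
_OPERATORS = ["op1", "op2", "op3", "op4", "op5"]
_SPECIES = [
    "E.coli", "A.tumefaciens", "S.lycopersicum", "P.hybrida",
    "A.majus", "O.ficus-indica", "H.sapiens",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level knobs; the defaults are the emulated study conditions."""

    seed: int
    n_pairs: int = 90
    n_replicates: int = 44
    amplicon_length: tuple[int, int] = (74, 907)
    primer_length: tuple[int, int] = (18, 25)
    gc_beta_shape: float = 10.0     # per-sequence GC fraction ~ Beta(shape, shape)
    intercept: float = DEFAULT_INTERCEPT
    signal_sd: float = DEFAULT_SIGNAL_SD
    noise_sd: float = DEFAULT_NOISE_SD
    curve_cycles: int = 40
    tm_method: str = "nearest_neighbor"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for all stochastic output")
        lo, hi = self.amplicon_length
        plo, phi = self.primer_length
        if not (0 < lo <= hi) or not (3 <= plo <= phi):
            raise ConfigurationError("infeasible length ranges")
        if lo < 2 * phi:
            raise ConfigurationError(
                "shortest amplicon must fit both primers "
                f"({lo} < 2 x {phi})"
            )
        if self.noise_sd < 0 or self.signal_sd < 0:
            raise ConfigurationError("noise and signal SDs must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def true_surface(z: np.ndarray) -> np.ndarray:
    """Smooth ground-truth response over six standardized covariates.

    A fixed, documented sum of three bivariate terms (two Gaussian-bump
    surfaces and one separable sine-cosine ripple), one per covariate pair
    of the additive model, so the model family can represent it.  *z* has
    shape (6, n): standardized (lengthSequence, gcSequence, primersLength,
    gcPrimers, gcImbalance, primerDimers).
    """
    def bumps(a, b):
        return np.exp(-((a - 0.3) ** 2 + (b + 0.2) ** 2)) - 0.6 * np.exp(
            -((a + 0.5) ** 2 + (b - 0.4) ** 2) / 0.5
        )

    return bumps(z[0], z[1]) + 0.8 * np.sin(z[2]) * np.cos(z[3]) + bumps(z[4], z[5])


_SURFACE_COVARIATES = [
    "lengthSequence", "gcSequence", "primersLength",
    "gcPrimers", "gcImbalance", "primerDimers",
]


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Feature table with true and noise-corrupted efficiencies.

    One row per reaction (n_pairs x n_replicates), in the standard feature
    CSV schema plus ``pairId`` and ``trueEfficiency`` columns.  The
    ground-truth surface is centred at ``config.intercept`` and scaled to
    ``config.signal_sd`` across pairs; observed efficiency adds Gaussian
    noise and truncates (clips) into [1, 2].  Byte-identical per seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.amplicon_length
    plo, phi = config.primer_length
    records = []
    metas = []
    for i in range(config.n_pairs):
        amp_gc = float(rng.beta(config.gc_beta_shape, config.gc_beta_shape))
        length = int(rng.integers(lo, hi + 1))
        amplicon = _random_sequence(rng, length, amp_gc)
        primers = PrimerPair(
            _random_sequence(
                rng, int(rng.integers(plo, phi + 1)),
                float(rng.beta(config.gc_beta_shape, config.gc_beta_shape)),
            ),
            _random_sequence(
                rng, int(rng.integers(plo, phi + 1)),
                float(rng.beta(config.gc_beta_shape, config.gc_beta_shape)),
            ),
        )
        meta = {
            "machine": _MACHINES[int(rng.integers(len(_MACHINES)))],
            "template": _TEMPLATES[int(rng.integers(len(_TEMPLATES)))],
            "source": _SOURCES[int(rng.integers(len(_SOURCES)))],
            "operator": _OPERATORS[int(rng.integers(len(_OPERATORS)))],
            "species": _SPECIES[int(rng.integers(len(_SPECIES)))],
            "var": f"line{int(rng.integers(1, 4))}",
        }
        metas.append(meta)
        records.append(
            extract_features(amplicon, primers, metadata=meta,
                             tm_method=config.tm_method)
        )

    pair_df = pd.DataFrame([r.to_dict() for r in records])
    z = np.vstack(
        [
            (pair_df[c].to_numpy(dtype=float) - pair_df[c].astype(float).mean())
            / max(pair_df[c].astype(float).std(ddof=0), 1e-12)
            for c in _SURFACE_COVARIATES
        ]
    )
    raw = true_surface(z)
    sd = raw.std(ddof=0)
    if config.signal_sd > 0 and sd > 0:
        signal = (raw - raw.mean()) / sd * config.signal_sd
    else:
        signal = np.zeros_like(raw)
    true_eff = config.intercept + signal

    rep = config.n_replicates
    full = pair_df.loc[pair_df.index.repeat(rep)].reset_index(drop=True)
    full.insert(0, "pairId", np.repeat([f"pair{i:03d}" for i in range(config.n_pairs)], rep))
    true_col = np.repeat(true_eff, rep)
    noise = (
        rng.normal(0.0, config.noise_sd, len(full)) if config.noise_sd > 0
        else np.zeros(len(full))
    )
    observed = np.clip(true_col + noise, 1.0, 2.0)
    full["trueEfficiency"] = true_col
    full["efficiency"] = observed
    return full[["pairId"] + FEATURE_COLUMNS + ["trueEfficiency"]]


def simulate_curve(
    true_e: float,
    f0: float = 2.0,
    amplitude: float = 10.0,
    cycles: int = 40,
    noise_sd: float = 0.0,
    seed: int | None = None,
    quant_cycle: float = 20.0,
) -> AmplificationCurve:
    """Raw (uncorrected) logistic amplification curve with efficiency *true_e*.

    The exponential phase saturates logistically into a plateau of height
    *amplitude* above the additive baseline *f0*; with the defaults the
    plateau is reached shortly after cycle 30.  *true_e* is the per-cycle
    fluorescence ratio at the standard quantification point (20% of the
    fluorescence at the second-derivative maximum), which a logistic places
    at a fixed fraction of its amplitude; the low-copy asymptotic ratio is
    marginally higher because a logistic's per-cycle ratio declines
    continuously.  ``true_e = 1`` yields a flat baseline-only trace.
    Optional noise is multiplicative Gaussian with SD *noise_sd* and
    requires a seed.
    """
    if not 1.0 <= true_e <= 2.0:
        raise ConfigurationError(f"true_e must be in [1, 2], got {true_e}")
    if cycles < 20:
        raise ConfigurationError(f"need at least 20 cycles, got {cycles}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ConfigurationError("noisy simulation requires a seed")
    cyc = np.arange(1, cycles + 1, dtype=float)
    if true_e == 1.0:
        flu = np.full_like(cyc, f0)
    else:
        # per-cycle ratio at the quantification point equals true_e:
        # (r + u*) / (1 + u*) = true_e with u* the logistic shape constant
        limit_ratio = true_e + QUANT_U * (true_e - 1.0)
        slope = 1.0 / math.log(limit_ratio)
        midpoint = quant_cycle - slope * math.log(QUANT_U)
        flu = logistic(cyc, f0, amplitude, midpoint, slope)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flu = flu * (1.0 + noise_sd * rng.standard_normal(len(cyc)))
    return AmplificationCurve(cyc, flu)
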