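"""Synthetic stand-ins for the curated database and for digitized kinetic traces.

The real curated table is a literature meta-dataset of GAG/protein aggregation
experiments. The generator emulates its statistical structure: sulfation
states 0–3 per disaccharide unit weighted toward the highly sulfated GAGs,
total solute molarity of tens to hundreds of mM, protein:GAG molar ratios
spanning roughly 0.1–100 on a log scale (most experiments at high GAG excess),
and a G response that is linear in sulfation and molarity and quadratic in the
molar ratio, plus i.i.d. Gaussian noise on the G scale.

Protein and GAG descriptor pools contain realistic, fully specified entries so
every generated row passes the database invariants; descriptor identities are
assigned independently of G, so any association between G and a protein
descriptor in synthetic data is noise by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    DatasetEntry,
    ExperimentalCondition,
    GagDescriptor,
    ProteinDescriptor,
)
from .exceptions import DomainError
from .kinetics import KineticTrace, exponential_model, sigmoid_model
from .multivariate import PredictiveModel

__all__ = [
    "GeneratorConfig",
    "generate_entries",
    "noise_for_target_r2",
    "generate_trace",
    "recovery_universe",
    "PROTEIN_POOL",
    "GAG_POOL",
]

#: realistic aggregating polypeptides (length, net charge at pH 7.5,
#: Lys+Arg count, folding status, disease association)
PROTEIN_POOL = [
    ProteinDescriptor("alpha-synuclein", 140, -9.0, 15, "natively_unfolded", True),
    ProteinDescriptor("gelsolin-173-243", 71, -4.0, 8, "natively_unfolded", True),
    ProteinDescriptor("amyloid-beta-1-40", 40, -3.0, 3, "natively_unfolded", True),
    ProteinDescriptor("beta2-microglobulin", 99, -1.0, 12, "globular", True),
    ProteinDescriptor("muscle-acylphosphatase", 98, 0.0, 13, "globular", False),
    ProteinDescriptor("ig-light-chain-VL", 110, -2.0, 10, "globular", True),
]

#: GAG descriptor pool keyed by sulfation state; (name, charges, uronic acid,
#: sulfate position, MW in Da, sampling weight within the level). Most GAGs
#: carry one extra negative charge from the uronic carboxylate; keratan sulfate
#: and dextran sulfate lack a uronic acid and hence the carboxylate.
GAG_POOL: dict[int, list[tuple[str, float, str, str, float, float]]] = {
    0: [
        ("hyaluronic-acid", 1.0, "glucuronic", "none", 1.5e6, 0.6),
        ("fully-desulfated-heparin", 1.0, "iduronic", "none", 12000.0, 0.4),
    ],
    1: [
        ("chondroitin-sulfate-A", 2.0, "glucuronic", "O", 25000.0, 0.5),
        ("dermatan-sulfate", 2.0, "iduronic", "O", 30000.0, 0.35),
        ("keratan-sulfate", 1.0, "none", "O", 15000.0, 0.15),
    ],
    2: [
        ("heparan-sulfate", 3.0, "iduronic", "mixed", 30000.0, 0.5),
        ("chondroitin-sulfate-E", 3.0, "glucuronic", "O", 60000.0, 0.5),
    ],
    3: [
        ("heparin", 4.0, "iduronic", "mixed", 15000.0, 0.85),
        ("dextran-sulfate", 3.0, "none", "O", 8000.0, 0.15),
    ],
}

#: half-time assigned to every no-GAG condition when back-filling the pair; G
#: is invariant to this base value
T_HALF_BASE_HOURS = 24.0


def recovery_universe():
    """Candidate universe for selection-consistency evaluation on synthetic data.

    The generating terms plus one pure-noise dummy decoy (uronic acid, which
    the generator assigns independently of G). charges_per_disaccharide is
    deliberately excluded: it tracks the sulfation state at r ≈ 0.97 in any
    realistic GAG pool, so no finite-sample procedure can reliably tell the
    two apart — substitution of that proxy is a property of the data, not of
    the selection algorithm, and is exercised by its own tests.
    """
    from .multivariate import ModelSpec

    return ModelSpec(
        predictors=[
            "sulfates_per_disaccharide",
            "solute_molarity",
            "protein_gag_molar_ratio",
            "uronic_acid=iduronic",
        ],
        quadratics=["protein_gag_molar_ratio"],
    )


@dataclass
class GeneratorConfig:
    """Sampling plan for a synthetic curated table.

    Defaults mirror the covariate regime of the literature database: sulfation
    weighted toward 2–3 sulfates per disaccharide, solute molarity uniform on
    [20, 300] mM, molar ratio log-uniform on [0.3, 60].
    """

    n_entries: int = 39
    coefficients: PredictiveModel = field(default_factory=PredictiveModel.published)
    noise_sd: float = 0.0
    sulfation_levels: Sequence[int] = (0, 1, 2, 3)
    sulfation_weights: Sequence[float] = (0.15, 0.15, 0.40, 0.30)
    molarity_range: tuple[float, float] = (20.0, 300.0)
    molar_ratio_range: tuple[float, float] = (0.3, 60.0)
    protein_conc_uM: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_entries < 1:
            raise DomainError("n_entries must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if not (len(self.sulfation_levels) == len(self.sulfation_weights) >= 2):
            raise DomainError("need >= 2 sulfation levels with matching weights")
        for lo, hi in (self.molarity_range, self.molar_ratio_range):
            if not 0 < lo < hi:
                raise DomainError("covariate ranges must be non-degenerate and positive")


def _sample_covariates(config: GeneratorConfig, rng: np.random.Generator):
    n = config.n_entries
    w = np.asarray(config.sulfation_weights, float)
    w = w / w.sum()
    p_s = rng.choice(np.asarray(config.sulfation_levels), size=n, p=w)
    p_b = rng.uniform(*config.molarity_range, size=n)
    lo, hi = config.molar_ratio_range
    p_mr = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    return p_s, p_b, p_mr


def generate_entries(config: GeneratorConfig) -> list[DatasetEntry]:
    """Draw a fully descriptor-complete synthetic entry table.

    G is the linear–quadratic predictive equation evaluated at the sampled
    covariates plus ``N(0, noise_sd²)``; the half-time pair is back-filled as
    ``(24 h, 24·exp(-G) h)`` so the stored-G invariant holds exactly. The same
    seed regenerates the identical list.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_s, p_b, p_mr = _sample_covariates(config, rng)
    m = config.coefficients
    signal = m.y0 + m.a * p_s + m.b * p_b + m.c * p_mr + m.c_prime * p_mr**2
    g = signal + rng.normal(0.0, config.noise_sd, size=config.n_entries)

    entries = []
    for i in range(config.n_entries):
        protein = PROTEIN_POOL[rng.integers(len(PROTEIN_POOL))]
        pool = GAG_POOL[int(p_s[i])]
        weights = np.array([t[5] for t in pool])
        name, charges, uronic, pos, mw, _ = pool[
            rng.choice(len(pool), p=weights / weights.sum())
        ]
        gag = GagDescriptor(
            name=name,
            sulfates_per_disaccharide=float(p_s[i]),
            charges_per_disaccharide=charges,
            uronic_acid=uronic,
            sulfation_position=pos,
            molecular_weight=mw,
        )
        t0 = T_HALF_BASE_HOURS
        tg = T_HALF_BASE_HOURS * math.exp(-g[i])
        entry = DatasetEntry(
            protein=protein,
            gag=gag,
            condition=ExperimentalCondition(
                solute_molarity=float(p_b[i]),
                protein_conc=config.protein_conc_uM,
                gag_conc=config.protein_conc_uM / float(p_mr[i]),
                protein_gag_molar_ratio=float(p_mr[i]),
                pH=7.4,
                temperature=37.0,
                buffer_text="synthetic",
            ),
            t_half_no_gag=t0,
            t_half_with_gag=tg,
            G=math.log(t0 / tg),
            time_unit="h",
            source="synthetic",
        )
        entry.validate()
        entries.append(entry)
    return entries


def noise_for_target_r2(config: GeneratorConfig, target_r2: float) -> float:
    """Noise standard deviation giving an expected R² near ``target_r2``.

    The deterministic part of G is evaluated over a covariate sample drawn
    with the config's seed; the returned sd is
    ``signal_sd * sqrt(1/target_r2 - 1)``, the value at which the signal
    variance is the target fraction of the total.
    """
    if not 0.0 < target_r2 < 1.0:
        raise DomainError(f"target_r2 must lie in (0, 1), got {target_r2}")
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_s, p_b, p_mr = _sample_covariates(config, rng)
    m = config.coefficients
    signal = m.y0 + m.a * p_s + m.b * p_b + m.c * p_mr + m.c_prime * p_mr**2
    signal_sd = float(np.std(signal, ddof=1))
    return signal_sd * math.sqrt(1.0 / target_r2 - 1.0)


def generate_trace(
    A0: float,
    A_inf: float,
    k_agg: float,
    t_half: float | None = None,
    lag: bool = True,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Forward-simulate an aggregation trace from the sigmoid or exponential model.

    Times are evenly spaced over ``[0, 2*t_half + 3/k_agg]`` (sigmoid) or
    ``[0, 5/k_agg]`` (exponential); Gaussian noise of sd ``noise_sd`` is added
    to the signals. The same seed reproduces the identical trace.
    """
    if n_points < 6:
        raise DomainError("a usable trace needs at least 6 points")
    if k_agg <= 0:
        raise DomainError("k_agg must be positive")
    rng = np.random.default_rng(seed)
    if lag:
        if t_half is None or t_half <= 0:
            raise DomainError("the sigmoid model needs a positive t_half")
        t_end = 2.0 * t_half + 3.0 / k_agg
        times = np.linspace(0.0, t_end, n_points)
        signals = sigmoid_model(times, A0, A_inf, k_agg, t_half)
    else:
        times = np.linspace(0.0, 5.0 / k_agg, n_points)
        signals = exponential_model(times, A0, A_inf, k_agg)
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=n_points)
    return KineticTrace(times=times, signals=signals)
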