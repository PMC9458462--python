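"""Synthetic data with the statistical structure of an ITPase-deficiency study.

Emulated inputs: a luciferase-like reference transcript, molecule populations
carrying stochastic inosine substitutions with a template-base preference
G>C>A>U, sequencing pileups under either a direct-RNA readout (inosine
elevates miscalls over a few-percent background) or a short-read readout
(inosine is reported as guanosine after reverse transcription), mass-spec
IMP-per-10^6-AMP measurements with replicate noise, and multi-peak polysome
absorbance traces.

All generators are deterministic given their seed. Component seeds are
derived from a single master seed via ``numpy.random.SeedSequence`` with
fixed spawn keys (see :data:`SEED_OFFSETS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import RNA_BASES, PileupTable, ProfileTrace, TranscriptRef
import pandas as pd

#: fixed spawn keys deriving each component stream from the master seed
SEED_OFFSETS = {
    "transcript": 0,
    "molecules_control": 1,
    "molecules_treated": 2,
    "pileup_control": 3,
    "pileup_treated": 4,
    "ms": 5,
    "polysome": 6,
}

#: default relative propensity for inosine to replace each template base;
#: any strictly ordered positive vector realises the G>C>A>U hierarchy
DEFAULT_TEMPLATE_WEIGHTS = {"G": 1.0, "C": 0.6, "A": 0.35, "U": 0.25}

#: default direct-RNA called-base distribution at an inosine position,
#: renormalized per position to exclude the template base
DEFAULT_INOSINE_ALT_CALLS = {"G": 0.5, "C": 0.25, "A": 0.15, "U": 0.10}


def rng_for(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component generator derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(SEED_OFFSETS[component],))
    )


@dataclass(frozen=True)
class MisincorporationModel:
    """Stochastic inosine substitution during transcription.

    ``overall_rate`` is the probability per transcribed base (e.g. 1/185);
    ``template_weights`` sets the relative propensity for inosine to replace
    each template base. Per-base probabilities are normalized so the
    composition-weighted mean equals ``overall_rate`` exactly:

        p(b) = overall_rate * w(b) / sum_b f(b) * w(b)

    making ``overall_rate`` directly comparable with '1 in N bases' figures.
    """

    overall_rate: float
    template_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_WEIGHTS)
    )

    def __post_init__(self):
        if not 0 <= self.overall_rate <= 1:
            raise ValueError("overall_rate must be a probability")
        if set(self.template_weights) != set(RNA_BASES):
            raise ValueError("template_weights must cover exactly A,C,G,U")
        if any(w <= 0 for w in self.template_weights.values()):
            raise ValueError("template weights must be positive")

    def per_base_probs(self, base_fractions: dict[str, float]) -> dict[str, float]:
        """Inosine probability per template base, for a given composition."""
        norm = sum(base_fractions[b] * self.template_weights[b] for b in RNA_BASES)
        if norm <= 0:
            raise ValueError("composition has no weight on any base")
        probs = {
            b: self.overall_rate * self.template_weights[b] / norm for b in RNA_BASES
        }
        too_high = [b for b, p in probs.items() if p > 1]
        if too_high:
            raise ValueError(
                f"overall_rate {self.overall_rate} implies per-base probability "
                f"> 1 at {too_high} for this composition"
            )
        return probs


@dataclass(frozen=True)
class ReadoutModel:
    """How base identity at each position translates into base calls.

    direct_rna: a canonical base is miscalled with ``background_miscall``
    (uniform over the other three bases); an inosine position is miscalled
    with ``inosine_miscall``, the called base drawn from ``inosine_alt_calls``
    renormalized to exclude the template base.

    short_read: inosine pairs with cytosine during reverse transcription and
    is read out as guanosine with probability 1; canonical bases are subject
    to ``background_miscall`` only.
    """

    mode: str
    background_miscall: float = 0.0
    inosine_miscall: float = 0.8
    inosine_alt_calls: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INOSINE_ALT_CALLS)
    )

    def __post_init__(self):
        if self.mode not in ("direct_rna", "short_read"):
            raise ValueError("mode must be 'direct_rna' or 'short_read'")
        for p in (self.background_miscall, self.inosine_miscall):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        total = sum(self.inosine_alt_calls.values())
        if not np.isclose(total, 1.0):
            raise ValueError("inosine_alt_calls must sum to 1")

    def call_probs(self, template_base: str, inosine_fraction: float) -> dict[str, float]:
        """Probability each base is called at a position, marginal over
        whether a read samples a canonical or inosine-bearing molecule."""
        others = [b for b in RNA_BASES if b != template_base]
        # canonical molecule
        canon = {b: self.background_miscall / 3 for b in others}
        canon[template_base] = 1 - self.background_miscall
        # inosine-bearing molecule
        if self.mode == "short_read":
            ino = {b: self.background_miscall / 3 for b in RNA_BASES if b != "G"}
            ino["G"] = 1 - self.background_miscall if template_base != "G" else 1.0
            if template_base == "G":
                # read as G: indistinguishable from the template, minus background
                ino = {b: self.background_miscall / 3 for b in others}
                ino["G"] = 1 - self.background_miscall
        else:
            alt_total = sum(self.inosine_alt_calls[b] for b in others)
            ino = {
                b: self.inosine_miscall * self.inosine_alt_calls[b] / alt_total
                for b in others
            }
            ino[template_base] = 1 - self.inosine_miscall
        f = inosine_fraction
        return {b: (1 - f) * canon[b] + f * ino[b] for b in RNA_BASES}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a two-condition synthetic study needs, under one seed."""

    seed: int
    depth: int = 100
    n_molecules: int = 20_000
    n_replicates: int = 3
    transcript_length: int = 1650
    base_probs: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in RNA_BASES}
    )
    rate_control: float = 0.0
    rate_treated: float = 1 / 185
    template_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_WEIGHTS)
    )
    readout: ReadoutModel = field(
        default_factory=lambda: ReadoutModel("direct_rna", background_miscall=0.03)
    )
    ms_noise_sd: float = 25.0
    polysome_peaks: tuple = (
        (8.0, 0.55, 0.6),   # 40S
        (12.0, 0.6, 0.9),   # 60S
        (17.0, 1.1, 1.2),   # 80S & disome (unresolved)
        (24.0, 3.2, 0.9),   # polysomes
    )
    polysome_baseline: float = 0.1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_transcript(length: int, base_probs: dict[str, float], seed: int,
                   ref_id: str = "synthetic_luc") -> TranscriptRef:
    """Random transcript of the given length and expected composition."""
    if length <= 0:
        raise ValueError("length must be positive")
    probs = np.array([base_probs.get(b, 0.0) for b in RNA_BASES], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("base_probs must sum to 1")
    rng = rng_for(seed, "transcript")
    seq = "".join(rng.choice(list(RNA_BASES), size=length, p=probs))
    return TranscriptRef(id=ref_id, seq=seq)


def simulate_molecules(ref: TranscriptRef, model: MisincorporationModel,
                       n_molecules: int, seed: int,
                       component: str = "molecules_treated") -> np.ndarray:
    """Per-position counts of molecules carrying inosine at that position.

    Each molecule takes independent Bernoulli inosine substitutions with the
    model's per-template-base probability, so the count at position i is
    Binomial(n_molecules, p(base_i)).
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    probs = model.per_base_probs(ref.base_fractions)
    p = np.array([probs[b] for b in ref.seq])
    rng = rng_for(seed, component)
    return rng.binomial(n_molecules, p)


def simulate_pileup(ref: TranscriptRef, incidence: np.ndarray,
                    readout: ReadoutModel, depth: int, seed: int,
                    component: str = "pileup_treated") -> PileupTable:
    """Draw a pileup table given per-position inosine incidence fractions.

    ``incidence`` holds, for every position, the fraction of molecules
    carrying inosine there (counts from :func:`simulate_molecules` divided by
    the number of molecules). Read calls at a position are i.i.d. draws from
    the readout model's marginal call distribution; read-level correlation
    along molecules is not modelled because all downstream statistics are
    positionwise.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    incidence = np.asarray(incidence, dtype=float)
    if incidence.shape != (ref.length,):
        raise ValueError("incidence must give a fraction for every position")
    if ((incidence < 0) | (incidence > 1)).any():
        raise ValueError("incidence fractions must lie in [0,1]")
    rng = rng_for(seed, component)
    rows = []
    for i, base in enumerate(ref.seq):
        probs = readout.call_probs(base, incidence[i])
        p = np.array([probs[b] for b in RNA_BASES])
        counts = rng.multinomial(depth, p / p.sum())
        by_base = dict(zip(RNA_BASES, counts))
        matches = int(by_base[base])
        rows.append({
            "pos": i + 1, "ref_base": base, "depth": depth,
            "matches": matches, "mismatches": int(depth - matches),
            "count_A": int(by_base["A"]), "count_C": int(by_base["C"]),
            "count_G": int(by_base["G"]), "count_U": int(by_base["U"]),
            "count_N": 0, "count_del": 0,
        })
    table = PileupTable(ref_id=ref.id, rows=pd.DataFrame(rows))
    return table.validate(ref, strict=True)


def simulate_two_condition(config: SimulationConfig) -> tuple[PileupTable, PileupTable]:
    """A (control, treated) pileup pair sharing transcript and readout.

    Control and treated use the configured misincorporation rates (e.g. 0 for
    a 0 mM ITP library, 1/185 for 10 mM) with independent sampling noise;
    all seeds derive deterministically from the master seed.
    """
    ref = gen_transcript(config.transcript_length, config.base_probs, config.seed)
    tables = []
    for rate, mol_comp, pile_comp in (
        (config.rate_control, "molecules_control", "pileup_control"),
        (config.rate_treated, "molecules_treated", "pileup_treated"),
    ):
        model = MisincorporationModel(rate, dict(config.template_weights))
        counts = simulate_molecules(ref, model, config.n_molecules, config.seed,
                                    component=mol_comp)
        incidence = counts / config.n_molecules if config.n_molecules else counts * 0.0
        tables.append(
            simulate_pileup(ref, incidence, config.readout, config.depth,
                            config.seed, component=pile_comp)
        )
    return tables[0], tables[1]


def simulate_ms(true_rate: float, f_A: float, sd: float, n: int, seed: int) -> list[float]:
    """Replicate IMP-per-10^6-AMP levels around the analytic level.

    The analytic level for a per-base inosine frequency r and A-base
    fraction f_A is r / f_A * 10^6; replicates add Gaussian noise with the
    given SD, truncated at zero (levels are non-negative).
    """
    if f_A <= 0:
        raise ValueError("f_A must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    level = true_rate / f_A * 1e6
    rng = rng_for(seed, "ms")
    draws = level + rng.normal(0.0, sd, size=n)
    return [float(max(0.0, x)) for x in draws]


def simulate_polysome_trace(peaks, baseline: float, noise_sd: float,
                            n_points: int, seed: int,
                            x_range: tuple[float, float] = (0.0, 35.0)) -> ProfileTrace:
    """Sum of Gaussian peaks on a flat baseline, optionally with noise.

    ``peaks`` is a list of (center, width, height); with ``noise_sd=0`` the
    trace is the analytic mixture. Identical peak centers are allowed.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    x = np.linspace(*x_range, n_points)
    y = np.full(n_points, float(baseline))
    for center, width, height in peaks:
        if width <= 0:
            raise ValueError("peak width must be positive")
        y += height * np.exp(-0.5 * ((x - center) / width) ** 2)
    if noise_sd > 0:
        rng = rng_for(seed, "polysome")
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return ProfileTrace(x, y)


def default_landmarks(config: SimulationConfig):
    """Apex positions (40S, 60S, 80S&disome) matching the default peak spec."""
    return tuple(p[0] for p in config.polysome_peaks[:3])
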