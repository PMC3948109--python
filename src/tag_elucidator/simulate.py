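"""Ground-truth simulator for every pipeline stage.

Generates TAG structures inside the one-long-two-short constraint box,
precursor/CID/OzID peak lists with the qualitative abundance structure the
pipeline exploits (sn-2 loss suppression, geometry-dependent
aldehyde:Criegee ratios), and multinomial choice-assay counts. All
randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import AdductSpec, FattyAcyl, TagStructure, ion_mz, tag_formula
from .cid import predict_cid_fragments
from .composition import CompositionConstraints
from .errors import ConfigError
from .io.peaklist import Spectrum
from .io.shorthand import format_lipid_shorthand
from .ozid import predict_ozid_products
from .stats import ChoiceAssay


@dataclass(frozen=True)
class SimulationConfig:
    """Structure priors, abundance rules and noise model for the simulator.

    The sn-2 suppression factor scales loss-channel intensities of the
    acyl sitting at sn-2 (qualitatively "less abundant"; the numeric
    default is a modeling choice). Geometry ratios are the simulated
    aldehyde:Criegee intensity ratios per double-bond geometry and match
    the pipeline's default reference table. ``mz_jitter`` must stay at or
    below half the fragment match tolerance for default recovery to hold.
    """

    constraints: CompositionConstraints = field(default_factory=CompositionConstraints)
    long_position_prior: dict[int, float] = field(
        default_factory=lambda: {9: 0.5, 7: 0.3, 6: 0.2}
    )
    p_cis: float = 0.8
    p_long_sn2: float = 0.2
    sn2_suppression: float = 0.3
    channel_intensity: dict[str, float] = field(
        default_factory=lambda: {
            "metalated-acid-loss": 1000.0,
            "neutral-acid-loss": 400.0,
        }
    )
    ozid_aldehyde_intensity: float = 600.0
    geometry_ratios: dict[str, float] = field(
        default_factory=lambda: {"cis": 2.0, "trans": 8.0}
    )
    n_noise_peaks: int = 5
    noise_intensity_sigma: float = 1.0
    mz_jitter: float = 0.05
    intensity_sigma: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p_cis <= 1 or not 0 <= self.p_long_sn2 <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")
        if not 0 < self.sn2_suppression < 1:
            raise ConfigError("sn2_suppression must lie in (0, 1)")
        if self.mz_jitter < 0 or self.n_noise_peaks < 0:
            raise ConfigError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationConfig":
        """Zero jitter, zero noise: simulated peaks equal predicted peaks."""
        return cls(
            n_noise_peaks=0, mz_jitter=0.0, intensity_sigma=0.0, **overrides
        )


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_structure(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> TagStructure:
    """Draw a TAG inside the constraint box with known positions/geometries."""
    rng = _as_rng(rng)
    c = config.constraints

    long_chain = _sample_long(config, rng)
    shorts = [_sample_short(c, config, rng) for _ in range(c.n_short)]

    if rng.random() < config.p_long_sn2:
        slots = (shorts[0], long_chain, shorts[1])
        assignment = "long-chain-at-sn-2"
    else:
        slots = (long_chain, shorts[0], shorts[1])
        assignment = "long-chain-at-sn-1/3"
    return TagStructure(acyls=slots, sn_assignment=assignment)


def _sample_long(config: SimulationConfig, rng: np.random.Generator) -> FattyAcyl:
    c = config.constraints
    n = int(rng.integers(c.long_carbons[0], c.long_carbons[1] + 1))
    d = int(rng.integers(c.long_db[0], c.long_db[1] + 1))
    d = min(d, n - 1)
    positions, geometries = _sample_annotation(
        n, d, config.long_position_prior, config.p_cis, rng
    )
    return FattyAcyl(n, d, positions, geometries)


def _sample_short(
    c: CompositionConstraints, config: SimulationConfig, rng: np.random.Generator
) -> FattyAcyl:
    n = int(rng.integers(c.short_carbons[0], c.short_carbons[1] + 1))
    d = int(rng.integers(c.short_db[0], c.short_db[1] + 1))
    if n < 3:
        d = 0  # an n-x position needs at least one methyl-side carbon
    positions = tuple([2] * d) if d else None  # short-chain dbs sit at n-2
    geometries = (
        tuple("cis" if rng.random() < config.p_cis else "trans" for _ in range(d))
        if d
        else None
    )
    # 5:1 models the branched tiglate; branching leaves the formula alone
    return FattyAcyl(n, d, positions, geometries, branched=(n == 5 and d == 1))


def _sample_annotation(
    n: int,
    d: int,
    prior: dict[int, float],
    p_cis: float,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...] | None, tuple[str, ...] | None]:
    if d == 0:
        return None, None
    feasible = sorted(x for x in prior if 2 <= x <= n - 1)
    if len(feasible) < d:
        feasible = list(range(2, n))
    weights = np.array([prior.get(x, 1.0) for x in feasible], dtype=float)
    weights /= weights.sum()
    positions = tuple(
        int(x) for x in rng.choice(feasible, size=d, replace=False, p=weights)
    )
    geometries = tuple(
        "cis" if rng.random() < p_cis else "trans" for _ in range(d)
    )
    return positions, geometries


@dataclass(frozen=True)
class SpectrumBundle:
    """Simulated spectra plus the ground truth that produced them."""

    structure: TagStructure
    adduct: AdductSpec
    precursor_mz: float
    precursor: Spectrum
    cid: Spectrum
    ozid: Spectrum

    def ground_truth(self) -> dict:
        positions = sorted(
            {x for a in self.structure.acyls for x in (a.db_positions or ())}
        )
        return {
            "shorthand": format_lipid_shorthand(self.structure),
            "composition": [str(a) for a in self.structure.composition()],
            "db_positions": positions,
            "sn_assignment": self.structure.sn_assignment,
            "adduct": self.adduct.cation,
            "precursor_mz": self.precursor_mz,
        }


def simulate_spectra(
    t: TagStructure,
    adduct: AdductSpec,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SpectrumBundle:
    """Simulate the precursor/CID/OzID peak lists for one structure."""
    config = config or SimulationConfig()
    rng = _as_rng(rng)
    precursor_mz = ion_mz(tag_formula(t), adduct)

    def jitter_mz(mz: float) -> float:
        if config.mz_jitter == 0:
            return mz
        return mz + float(rng.uniform(-config.mz_jitter, config.mz_jitter))

    def jitter_intensity(value: float) -> float:
        if config.intensity_sigma == 0:
            return value
        return value * float(rng.lognormal(0.0, config.intensity_sigma))

    precursor_peaks = [(jitter_mz(precursor_mz), jitter_intensity(1000.0))]

    # CID: two loss channels per distinct acyl; sn-2 occupant suppressed
    suppressed_key = _sn2_occupant_key(t)
    cid_peaks = []
    for fragment in predict_cid_fragments(t.composition(), precursor_mz, adduct):
        base = config.channel_intensity[fragment.channel]
        if suppressed_key is not None and fragment.parent_acyl.key == suppressed_key:
            base *= config.sn2_suppression
        cid_peaks.append((jitter_mz(fragment.mz), jitter_intensity(base)))

    # OzID: one aldehyde/Criegee pair per distinct double-bond position
    geometry_by_position: dict[int, str] = {}
    for acyl in t.acyls:
        for i, x in enumerate(acyl.db_positions or ()):
            geometry = (
                acyl.db_geometries[i] if acyl.db_geometries else "cis"
            )
            geometry_by_position.setdefault(x, geometry)
    ozid_peaks = []
    for pair in predict_ozid_products(precursor_mz, sorted(geometry_by_position)):
        geometry = geometry_by_position[pair.n_x]
        ratio = config.geometry_ratios.get(geometry, 2.0)
        aldehyde = config.ozid_aldehyde_intensity
        ozid_peaks.append((jitter_mz(pair.aldehyde_mz), jitter_intensity(aldehyde)))
        ozid_peaks.append(
            (jitter_mz(pair.criegee_mz), jitter_intensity(aldehyde / ratio))
        )

    for peaks in (precursor_peaks, cid_peaks, ozid_peaks):
        peaks.extend(_noise_peaks(peaks, precursor_mz, config, rng))

    return SpectrumBundle(
        structure=t,
        adduct=adduct,
        precursor_mz=precursor_mz,
        precursor=Spectrum("precursor", tuple(precursor_peaks), precursor_mz, adduct),
        cid=Spectrum("CID", tuple(cid_peaks), precursor_mz, adduct),
        ozid=Spectrum("OzID", tuple(ozid_peaks), precursor_mz, adduct),
    )


def _sn2_occupant_key(t: TagStructure) -> tuple[int, int] | None:
    if t.sn_assignment == "long-chain-at-sn-2":
        return t.long_chain.key
    if t.sn_assignment in ("long-chain-at-sn-1/3", "fully-resolved"):
        return t.acyls[1].key  # slot order is sn-1/2/3 when resolved
    return None


def _noise_peaks(
    true_peaks: list[tuple[float, float]],
    precursor_mz: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    if config.n_noise_peaks == 0 or not true_peaks:
        return []
    median_true = float(np.median([i for _, i in true_peaks]))
    out = []
    for _ in range(config.n_noise_peaks):
        mz = float(rng.uniform(100.0, precursor_mz + 20.0))
        intensity = float(
            rng.lognormal(np.log(0.1 * median_true), config.noise_intensity_sigma)
        )
        out.append((mz, min(intensity, 0.9 * median_true)))
    return out


def simulate_choice_assay(
    n: int,
    p_choice_a: float,
    p_no_choice: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ChoiceAssay:
    """Draw multinomial (A, B, no-choice) counts for ``n`` trials."""
    if not 0 <= p_choice_a <= 1 or not 0 <= p_no_choice <= 1:
        raise ConfigError("probabilities must lie in [0, 1]")
    if p_choice_a + p_no_choice > 1 + 1e-12:
        raise ConfigError("p_choice_a + p_no_choice must not exceed 1")
    rng = _as_rng(rng)
    p_b = max(0.0, 1.0 - p_choice_a - p_no_choice)
    a, b, nc = rng.multinomial(n, [p_choice_a, p_b, p_no_choice])
    return ChoiceAssay(int(a), int(b), int(nc))
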