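"""Generative model of droplet digital PCR plates.

Emulates the statistics the downstream analysis relies on: Poisson
partitioning of template molecules into ~16,000 droplets per well, Gaussian
fluorescence clusters per amplitude-multiplexed target band, optional rain
and false-positive events, dilution series at fixed total input, and
negative-control plates. Thermal cycling, probe chemistry and droplet
generation failure modes are out of scope.

A droplet containing a template molecule of target ``t`` is positive for
that band with probability ``p = 1 - exp(-c * V_d)`` where ``c`` is the
template concentration in copies/uL of reaction and ``V_d`` the droplet
volume in uL; occupancy of different templates is independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DROPLET_VOLUME_NL,
    ELUATE_LOADED_UL,
    N_DROPLETS_DEFAULT,
    PG_PER_HGE,
    REACTION_VOLUME_UL,
)
from .containers import DropletWell


@dataclass(frozen=True)
class TargetBand:
    """One amplitude-multiplexed FAM band: positive-cluster mean and SD."""

    target_id: str
    mean_fam: float
    sd_fam: float


@dataclass
class AmplitudeModel:
    """Synthetic fluorescence-cluster geometry for one multiplexed assay.

    Amplitude units are arbitrary; the instrument's scale is not published,
    so the defaults are a synthetic convention chosen for >=5 SD separation
    between the negative cluster and every positive band, and between bands.

    ``rain_fraction`` is the proportion of template-positive droplets whose
    FAM amplitude is smeared uniformly between the negative mean and their
    band mean (partial amplification). ``fp_rate`` is the expected number of
    template-free droplets per well spuriously appearing in a random target
    band (probe cross-reactivity); both default to 0 — ideal separation.
    """

    negative_mean_fam: float = 1000.0
    negative_sd_fam: float = 90.0
    negative_mean_hex: float = 900.0
    negative_sd_hex: float = 80.0
    target_bands: list[TargetBand] = field(default_factory=list)
    reference_positive_mean_hex: float = 4500.0
    reference_positive_sd_hex: float = 150.0
    rain_fraction: float = 0.0
    fp_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rain_fraction <= 1.0:
            raise ValueError("rain_fraction must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        bands = sorted(self.target_bands, key=lambda b: b.mean_fam)
        for band in bands:
            sep = band.mean_fam - self.negative_mean_fam
            if sep < 5 * max(band.sd_fam, self.negative_sd_fam):
                raise ValueError(
                    f"band {band.target_id} closer than 5 SD to the negative cluster"
                )
        for lo, hi in zip(bands, bands[1:]):
            if hi.mean_fam - lo.mean_fam < 5 * max(lo.sd_fam, hi.sd_fam):
                raise ValueError(
                    f"bands {lo.target_id}/{hi.target_id} closer than 5 SD"
                )
        hex_sep = self.reference_positive_mean_hex - self.negative_mean_hex
        if hex_sep < 5 * max(self.reference_positive_sd_hex, self.negative_sd_hex):
            raise ValueError("reference HEX band closer than 5 SD to negative cluster")

    @classmethod
    def default(cls, targets: list[str], **kwargs) -> "AmplitudeModel":
        """Evenly spaced bands between 3000 and 7000 a.u. for ``targets``.

        Band order follows the ``targets`` list, ascending in FAM amplitude.
        """
        n = len(targets)
        if n == 0:
            return cls(target_bands=[], **kwargs)
        means = np.linspace(3000.0, 7000.0, n) if n > 1 else np.array([5000.0])
        bands = [TargetBand(t, float(m), 120.0) for t, m in zip(targets, means)]
        return cls(target_bands=bands, **kwargs)

    def band(self, target_id: str) -> TargetBand:
        for b in self.target_bands:
            if b.target_id == target_id:
                return b
        raise KeyError(f"no amplitude band for target {target_id!r}")


@dataclass(frozen=True)
class WellSpec:
    """Physical geometry of one ddPCR well."""

    n_droplets: int = N_DROPLETS_DEFAULT
    droplet_volume_nl: float = DROPLET_VOLUME_NL
    reaction_volume_ul: float = REACTION_VOLUME_UL
    eluate_loaded_ul: float = ELUATE_LOADED_UL

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")
        if self.n_droplets * self.droplet_volume_nl > self.reaction_volume_ul * 1000:
            raise ValueError("droplets exceed the reaction volume")

    @property
    def droplet_volume_ul(self) -> float:
        return self.droplet_volume_nl * 1e-3


def _rng_for_well(seed: int, well_index: int) -> np.random.Generator:
    # One plate seed; per-well streams split off deterministically.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(well_index,)))


def simulate_well(
    target_concentrations: dict[str, float],
    reference_concentration: float,
    amplitude_model: AmplitudeModel,
    well_spec: WellSpec,
    rng: np.random.Generator | int,
    *,
    well_id: str = "A01",
    sample_id: str = "synthetic",
    role: str = "sample",
    replicate_group: str = "",
    biofluid_volume_ml: float | None = None,
) -> DropletWell:
    """Simulate one well at the given template concentrations (copies/uL).

    Each droplet is occupied by each template independently with
    ``p = 1 - exp(-c * V_d)``. Droplets positive for exactly one target draw
    FAM from that band; droplets co-occupied by several targets emit the sum
    of the band offsets (landing above every single band, as combined
    amplitudes do in amplitude multiplexing). HEX behaves analogously with a
    single reference band. False positives and rain per the amplitude model.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    for t, c in target_concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for target {t}")
        amplitude_model.band(t)  # must exist
    if reference_concentration < 0:
        raise ValueError("negative reference concentration")

    m = amplitude_model
    n = well_spec.n_droplets
    vd = well_spec.droplet_volume_ul

    fam = rng.normal(m.negative_mean_fam, m.negative_sd_fam, n)
    hexv = rng.normal(m.negative_mean_hex, m.negative_sd_hex, n)

    occupancy: dict[str, np.ndarray] = {}
    for t, c in target_concentrations.items():
        p = 1.0 - np.exp(-c * vd)
        occupancy[t] = rng.random(n) < p
    ref_pos = rng.random(n) < 1.0 - np.exp(-reference_concentration * vd)

    n_targets_in = np.zeros(n, dtype=int)
    fam_offset = np.zeros(n)
    band_sd = np.zeros(n)
    for t, occ in occupancy.items():
        band = m.band(t)
        n_targets_in += occ
        fam_offset[occ] += band.mean_fam - m.negative_mean_fam
        band_sd[occ] = np.maximum(band_sd[occ], band.sd_fam)
    any_target = n_targets_in > 0
    k = int(any_target.sum())
    if k:
        fam[any_target] = (
            m.negative_mean_fam
            + fam_offset[any_target]
            + rng.normal(0.0, 1.0, k) * band_sd[any_target]
        )
    nref = int(ref_pos.sum())
    if nref:
        hexv[ref_pos] = rng.normal(
            m.reference_positive_mean_hex, m.reference_positive_sd_hex, nref
        )

    truth = {f"n_template:{t}": int(occ.sum()) for t, occ in occupancy.items()}
    truth["n_template_reference"] = nref

    # Rain: a fraction of single-target droplets smeared below their band.
    if m.rain_fraction > 0 and k:
        single = any_target & (n_targets_in == 1)
        rain_mask = single & (rng.random(n) < m.rain_fraction)
        idx = np.flatnonzero(rain_mask)
        if idx.size:
            fam[idx] = rng.uniform(m.negative_mean_fam, fam[idx])
        truth["n_rain"] = int(idx.size)

    # False positives: template-free droplets relabelled into a random band.
    n_fp = 0
    if m.fp_rate > 0 and m.target_bands:
        n_fp = int(rng.poisson(m.fp_rate))
        free = np.flatnonzero(~any_target)
        n_fp = min(n_fp, free.size)
        if n_fp:
            chosen = rng.choice(free, size=n_fp, replace=False)
            bands = [m.target_bands[i] for i in rng.integers(0, len(m.target_bands), n_fp)]
            fam[chosen] = [rng.normal(b.mean_fam, b.sd_fam) for b in bands]
            for b, i in zip(bands, chosen):
                key = f"n_false_positive:{b.target_id}"
                truth[key] = truth.get(key, 0) + 1
    truth["n_false_positive_total"] = n_fp

    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        role=role,
        fam=fam,
        hex=hexv,
        replicate_group=replicate_group,
        biofluid_volume_ml=biofluid_volume_ml,
        truth=truth,
    )


def simulate_dilution_series(
    dilutions: list[float] = (1e-1, 1e-2, 1e-3, 1e-4),
    total_mass_ng: float = 10.0,
    assay: str = "target",
    amplitude_model: AmplitudeModel | None = None,
    well_spec: WellSpec | None = None,
    seed: int = 0,
) -> list[DropletWell]:
    """Ten-fold dilution series of tumor gDNA in normal gDNA, one well/step.

    At each step the tumor fraction contributes
    ``total_mass_ng * dilution * 1000 / 3.3`` target copies to the well,
    while the reference assay sees the full input mass (tumor + normal
    background), emulating a constant 10 ng load.
    """
    dilutions = list(dilutions)
    if total_mass_ng <= 0:
        raise ValueError("total mass must be positive")
    if any(not 0 < d <= 1 for d in dilutions):
        raise ValueError("dilutions must lie in (0, 1]")
    if any(b >= a for a, b in zip(dilutions, dilutions[1:])):
        raise ValueError("dilutions must be strictly decreasing")
    well_spec = well_spec or WellSpec()
    amplitude_model = amplitude_model or AmplitudeModel.default([assay])

    ref_copies = total_mass_ng * 1000.0 / PG_PER_HGE
    wells = []
    for i, d in enumerate(dilutions):
        tumor_copies = total_mass_ng * d * 1000.0 / PG_PER_HGE
        c_target = tumor_copies / well_spec.reaction_volume_ul
        c_ref = ref_copies / well_spec.reaction_volume_ul
        well = simulate_well(
            {assay: c_target},
            c_ref,
            amplitude_model,
            well_spec,
            _rng_for_well(seed, i),
            well_id=f"D{i + 1:02d}",
            sample_id=f"dilution_{d:g}",
            role="PC_gDNA",
        )
        well.truth["dilution"] = d
        well.truth["tumor_mass_pg"] = total_mass_ng * d * 1000.0
        wells.append(well)
    return wells


def simulate_nc_plate(
    n_wells: int = 12,
    fp_rate: float = 0.0,
    amplitude_model: AmplitudeModel | None = None,
    well_spec: WellSpec | None = None,
    seed: int = 0,
    reference_concentration: float = 50.0,
) -> list[DropletWell]:
    """Negative-control cfDNA wells: reference template, no true target.

    Target-band droplets appear only as Poisson(``fp_rate``) false positives
    per well. ``reference_concentration`` (copies/uL of reaction) stands in
    for the donor-plasma cfDNA background.
    """
    if n_wells < 1:
        raise ValueError("need at least one NC well")
    if fp_rate < 0:
        raise ValueError("fp_rate must be non-negative")
    well_spec = well_spec or WellSpec()
    amplitude_model = amplitude_model or AmplitudeModel.default(["target"])

    import dataclasses

    model = dataclasses.replace(amplitude_model, fp_rate=fp_rate)
    wells = []
    for i in range(n_wells):
        wells.append(
            simulate_well(
                {b.target_id: 0.0 for b in model.target_bands},
                reference_concentration,
                model,
                well_spec,
                _rng_for_well(seed, i),
                well_id=f"N{i + 1:02d}",
                sample_id="NC_cfDNA",
                role="NC_cfDNA",
            )
        )
    return wells


def simulate_control_wells(
    panel: list[str],
    amplitude_model: AmplitudeModel,
    well_spec: WellSpec,
    seed: int,
    pc_concentration: float = 150.0,
    reference_concentration: float = 150.0,
) -> list[DropletWell]:
    """NC gDNA / PC gDNA / NTC triplet used to derive gates on each plate."""
    rng_nc = _rng_for_well(seed, 1001)
    rng_pc = _rng_for_well(seed, 1002)
    rng_ntc = _rng_for_well(seed, 1003)
    nc = simulate_well(
        {t: 0.0 for t in panel},
        reference_concentration,
        amplitude_model,
        well_spec,
        rng_nc,
        well_id="C01",
        sample_id="NC_gDNA",
        role="NC_gDNA",
    )
    pc = simulate_well(
        {t: pc_concentration for t in panel},
        reference_concentration,
        amplitude_model,
        well_spec,
        rng_pc,
        well_id="C02",
        sample_id="PC_gDNA",
        role="PC_gDNA",
    )
    ntc = simulate_well(
        {t: 0.0 for t in panel},
        0.0,
        amplitude_model,
        well_spec,
        rng_ntc,
        well_id="C03",
        sample_id="NTC",
        role="NTC",
    )
    return [nc, pc, ntc]
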