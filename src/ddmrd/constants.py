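"""Physical and protocol constants shared across the pipeline.

All values are overridable at call sites; these are the defaults the
workflow was designed around.
"""

#: Mass of one haploid human genome in picograms. Used to convert between
#: copies (haploid genomic equivalents, hGE) and DNA mass.
PG_PER_HGE = 3.3

#: Nominal droplet volume of the QX200 droplet generator, in nanolitres.
DROPLET_VOLUME_NL = 0.85

#: Default number of accepted droplets per well.
N_DROPLETS_DEFAULT = 16000

#: ddPCR reaction volume per well, in microlitres.
REACTION_VOLUME_UL = 22.0

#: Volume of cfDNA eluate loaded per well, in microlitres.
ELUATE_LOADED_UL = 11.0

#: Fraction of the 40 uL cfDNA eluate consumed by a triplicate run
#: (3 x 11 uL = 33 of 40 uL); copies detected are scaled up by its inverse
#: to express copies in the full eluate.
INPUT_FRACTION = 33.0 / 40.0

#: Minimum number of mutant (FAM) droplets required for a positive or
#: trace-positive call.
MIN_POSITIVE_DROPLETS = 3

#: Number of negative-control cfDNA wells per plate used for assay
#: false-positive-rate estimation.
NC_WELLS_DEFAULT = 12

#: Conversion factor from false-positive events/well to events/mL of
#: negative-control plasma. Configurable: the published volumes do not pin
#: the factor down unambiguously.
FPR_EVENTS_PER_ML_FACTOR = 1.375


def droplet_volume_ul(droplet_volume_nl: float = DROPLET_VOLUME_NL) -> float:
    """Droplet volume in microlitres, the unit concentration math uses."""
    return droplet_volume_nl * 1e-3
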