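"""Reference bookkeeping for the deposited MS multi-omics cohort.

The real study data (42 individuals; small-RNA profiles from plasma, PBMCs,
CSF cells and cell-free CSF through the Small-seq and MINTmap pipelines,
plus a CSF-cell methylome) are deposited at the Swedish National Data
Service, accession doi:10.5878/c1mq-9r62, and are not shipped here.  This
module records the published post-filter feature counts and reduced-model
selection tallies for that cohort, used by the reporting layer as a
consistency reference and by the percentage arithmetic helpers.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: accession of the deposited cohort
COHORT_ACCESSION = "doi:10.5878/c1mq-9r62"

#: post-filter feature counts per block entering the integration
COHORT_FEATURE_COUNTS: dict[str, int] = {
    "pbmc_smallseq": 21615,
    "pbmc_mintmap": 3645,
    "plasma_smallseq": 1535,
    "plasma_mintmap": 323,
    "csf_cells_smallseq": 1638,
    "csf_cells_mintmap": 515,
    "csf_free_smallseq": 818,
    "csf_free_mintmap": 250,
    "csf_cells_methylome": 143013,
}

#: total feature count entering the integration
COHORT_TOTAL_FEATURES = 173352

#: cohort composition
N_INDIVIDUALS = 42
N_SOURCES = 4              # plasma, PBMCs, CSF cells, cell-free CSF
N_RNA_PIPELINES = 2        # Small-seq and MINTmap per source
N_METHYLOME_PROFILES_PER_INDIVIDUAL = 1

#: reduced-model (44-feature) selection tallies by pipeline and source
REDUCED_SELECTION_BY_SOURCE: dict[str, dict[str, int]] = {
    "smallseq": {"plasma": 19, "csf_free": 11, "csf_cells": 2},
    "mintmap": {"csf_cells": 6, "csf_free": 5, "plasma": 1},
}

#: reduced-model tRF class tallies among the MINTmap-derived selections
REDUCED_TRF_CLASSES: dict[str, int] = {"i-tRF": 4, "5'-tRF": 3, "3'-tRF": 4, "3'-half": 1}


def percentage(count: int, total: int) -> float:
    """count / total as a percentage rounded half-up to one decimal.

    ``percentage(19, 32) == 59.4``; ``percentage(2, 32) == 6.3``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) / Decimal(total) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def profile_count(n_individuals: int = N_INDIVIDUALS, n_sources: int = N_SOURCES,
                  n_rna_pipelines: int = N_RNA_PIPELINES) -> int:
    """Number of molecular profiles: RNA profiles per source and pipeline
    plus one methylome per individual."""
    return (n_individuals * n_sources * n_rna_pipelines
            + n_individuals * N_METHYLOME_PROFILES_PER_INDIVIDUAL)
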