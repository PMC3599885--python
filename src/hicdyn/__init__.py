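"""hicdyn: differential chromatin-interaction analysis from binned Hi-C data.

The pipeline: bin the genome into fixed-width windows, build symmetric
contact matrices from read pairs (deduplicated), normalize to
observed/expected Z-scores, measure per-bin interaction frequency and call
hot/cold regions, quantify condition differences with the bounded
relative-ratio statistic (saturating at +/-2 for condition-exclusive
contacts), classify strong changes into gain/loss x intra/inter, and
integrate the calls with epigenomic tracks, binding peaks, rearrangement
break-points and expression.
"""

from .binning import BinnedGenome, bin_genome
from .contacts import ContactMatrix, build_contact_matrix, canonicalize_pairs
from .zscores import ZScoreMatrix, expected_matrix, zscore_transform
from .frequency import (
    FrequencyProfile,
    RegionCall,
    call_regions,
    correlation_matrices,
    frequency_table,
    interaction_frequency,
)
from .differential import (
    DifferentialCall,
    RelativeRatioMatrix,
    classify_differential,
    exp_strength,
    fold_change_to_ratio,
    gain_loss_profile,
    ratio_to_fold_change,
    relative_ratio,
    relative_ratio_matrix,
)
from .integration import (
    ChiSquareResult,
    EnrichmentResult,
    GeneModel,
    GenePartition,
    OverlapResult,
    SignalSummary,
    aggregate_signal,
    breakpoint_overlap,
    de_enrichment_chisq,
    enrichment_table,
    enrichment_test,
    expression_correlation,
    gene_bins,
    partition_gene,
    peaks_per_bin,
    rank_association,
    summarize_gene_counts,
)
from .simulate import (
    Annotations,
    SimulationConfig,
    SimulationTruth,
    ground_truth,
    null_config,
    simulate_annotations,
    simulate_pairs,
    simulate_tracks,
)
from .config import RunConfig

__version__ = "0.1.0"


def contact_zscores(pairs, genome, condition="", dedup=True, mode="distance"):
    """Read pairs -> Z-score matrix: build, normalize, standardize in one call."""
    contacts = build_contact_matrix(pairs, genome, dedup=dedup, condition=condition)
    expected, usable = expected_matrix(contacts, mode=mode)
    return zscore_transform(contacts, expected, usable)


__all__ = [name for name in dir() if not name.startswith("_")]
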