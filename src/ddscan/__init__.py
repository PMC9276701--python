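"""ddscan: target scanning and conversion calling for DddA-derived
cytosine base editors (dimeric DdCBE and monomeric mDdCBE) on organellar
genomes."""

__version__ = "0.1.0"

from importlib import resources as _resources

from .calling import (
    CallerParams,
    OffTargetSummary,
    PileupResult,
    PositionConversion,
    pileup_conversions,
    quantify_on_target,
    summarize_offtarget,
)
from .design import RankedDesign, TargetDesignReport, WindowParams, design_for_target
from .genome import (
    Genome,
    Interval,
    SequenceError,
    fetch_window,
    read_fasta,
    read_genome,
    reverse_complement,
)
from .profiling import (
    EditingWindowProfile,
    SiteProfile,
    aggregate_window,
    align_profile_to_site,
)
from .scan import (
    DdCBEDesign,
    EditabilityReport,
    MDdCBEDesign,
    ScanParams,
    TALESite,
    TCMotif,
    editability_report,
    enumerate_tale_sites,
    find_ddcbe_designs,
    find_mddcbe_designs,
    find_tc_motifs,
)
from .simulate import (
    EditSpec,
    GenomeSpec,
    PlantDdCBEPair,
    PlantMDdCBESite,
    PlantTCMotif,
    TruthRecord,
    make_genome,
    simulate_reads,
)


def bundled_mtdna_path():
    """Path to the bundled human mitochondrial genome FASTA (NC_001807.4).

    This is the older 16,571-bp human mtDNA reference, included because it
    is redistributable sequence data; supply the rCRS (NC_012920) FASTA for
    exact revised-reference coordinates.
    """
    return _resources.files("ddscan").joinpath("data/human_mtDNA_NC_001807.fasta")
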