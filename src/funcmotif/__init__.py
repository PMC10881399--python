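"""funcmotif: candidate functional TF-motif discovery in enhancer sequences.

The pipeline: simulate (or load) an enhancer dataset, train a convolutional
enhancer classifier, derive strand-aggregated per-nucleotide importance
scores, calibrate PWM score cutoffs to an empirical false-positive rate,
and call functional motifs where PWM matches coincide with high-importance
positions.
"""

from importlib import resources

from .intervals import GenomicInterval, PeakRecord, reverse_complement
from .motifs import (
    CutoffCalibration,
    MotifMatch,
    PWMModel,
    calibrate_cutoff,
    load_jaspar,
    scan,
    score_window,
)
from .dataset import (
    DatasetConfig,
    LabelledExample,
    assign_splits,
    build_dataset,
    build_positives,
    encode_onehot,
    sample_gc_matched_negatives,
)
from .classifier import (
    ClassifierConfig,
    TrainedClassifier,
    evaluate_auroc,
    train,
)
from .attribution import (
    ImportanceTrack,
    TopPositionSet,
    aggregate_strands,
    attribute_window,
    importance_scores,
    top_fraction_positions,
)
from .functional import (
    FunctionalMotifCall,
    call_functional,
    overlap_with_top_set,
    recovery_report,
)
from .synthetic import (
    PlantedMotifTruth,
    SyntheticGenomeConfig,
    SyntheticPeakSetConfig,
    generate_genome,
    plant_enhancers,
    write_fixture,
)

__version__ = "0.1.0"


def packaged_motifs_path():
    """Path to the shipped synthetic E-box/ETS JASPAR fixture.

    These are synthetic matrices shaped like the TCF3 E-box and ELK1 ETS
    motifs (not the JASPAR database entries), for fully offline runs.
    """
    return resources.files("funcmotif") / "data" / "synthetic_motifs.jaspar"
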