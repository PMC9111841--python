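"""mycoquant: automated scoring of arbuscular mycorrhizal colonization on gridded slides.

The package implements the magnified-intersections workflow on digital
slide photographs: the slide grid is deskewed from a gradient-orientation
histogram, grid-line crossings are located from projection-profile peaks,
the ~150 px sampling area around each crossing is classified into one of
four colonization classes (vesicles, arbuscules, negative, no-root), and
arbuscular / vesicular colonization proportions are computed from the
class tallies.
"""

from .core import (
    ClassLabel,
    IntersectionBox,
    RunConfig,
    SamplingArea,
    SlideImage,
)
from .io import read_image, write_image, write_results, read_results
from .rotation import (
    GradientField,
    DirectionHistogram,
    RotationEstimate,
    compute_gradients,
    direction_histogram,
    estimate_rotation_angle,
    normalize_rotation,
    rotate_image,
    rotate_points,
)
from .grid import (
    GridLine,
    ProjectionProfile,
    DetectionResult,
    projection_profiles,
    detect_edge_peaks,
    pair_edges_to_lines,
    intersections_from_lines,
    detect_intersections,
)
from .classify import (
    FeatureVector,
    ClassifierModel,
    EvaluationReport,
    extract_features,
    train_classifier,
    classify,
    augment_dataset,
    cross_validate,
    save_model,
    load_model,
)
from .colonization import ClassCounts, ColonizationResult, count_classes, colonization_degrees
from .evaluate import MatchReport, iou, match_detections, precision_at, recall_at
from .synth import (
    SlidePhantomSpec,
    SlideGroundTruth,
    generate_slide,
    generate_classification_set,
    generate_failure_suite,
)

__version__ = "0.1.0"
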