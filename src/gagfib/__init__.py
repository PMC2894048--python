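"""gagfib: how glycosaminoglycans accelerate amyloid fibril formation.

A pipeline from digitized aggregation kinetics to the acceleration statistic
G = ln(t_half without GAG / t_half with GAG), through univariate correlation
analyses, to a multivariate linear-quadratic predictive model of G with
bootstrap and jackknife validation, plus a synthetic-data generator emulating
the curated literature database.
"""

from importlib import resources

from .data_model import (
    DatasetEntry,
    ExperimentalCondition,
    GagDescriptor,
    ProteinDescriptor,
    dataset_summary,
    encode_dummies,
    entries_to_frame,
    load_dataset,
    load_schema,
    save_dataset,
)
from .kinetics import (
    FittedKinetics,
    KineticTrace,
    compute_G,
    fit_trace,
    g_from_trace_pair,
    half_time_from_rate_and_lag,
)
from .model import GagAccelerationModel, GagAccelerationResults
from .multivariate import (
    PREDICTIVE_SPEC,
    ModelSpec,
    PredictiveModel,
    RegressionFit,
    build_design,
    ols_fit,
    optimal_molar_ratio,
    predict_G,
    select_model,
)
from .synthetic_data import GeneratorConfig, generate_entries, generate_trace, noise_for_target_r2
from .validation import bootstrap_validate, jackknife_validate, prediction_report

__version__ = "0.1.0"


def demo_dataset_path():
    """Path to the bundled synthetic 39-entry database (TSV)."""
    return resources.files("gagfib").joinpath("data", "synthetic_database.tsv")


def load_demo_dataset():
    """Load the bundled synthetic stand-in for the curated literature table.

    39 entries drawn from the generator at a fixed seed with noise calibrated
    so the predictive equation explains roughly three quarters of the variance.
    The table is synthetic: its numbers illustrate the pipeline, they are not
    literature measurements.
    """
    with resources.as_file(demo_dataset_path()) as p:
        return load_dataset(p)
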