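"""trfscape: tRNA-derived fragment calling and developmental profiling.

Identify tRFs in small-RNA sequencing libraries by exact, CCA-tail-aware
mapping to mitochondrial and nuclear mature tRNAs, classify them by
structural region on the parental cloverleaf, and profile their
expression across developmental stages with spike-in normalization.
Includes a synthetic-data generator with full ground truth.
"""

__version__ = "0.1.0"

from .config import RunConfig
from .read_filtering import UniqueRead
from .synthetic_data import GenomeBundle, SimulationConfig, generate_genome, simulate_reads
from .trf_classification import classify_region, main_region, top_variants
from .trf_mapping import TRFRecord, call_trfs
from .trna_catalog import MatureTRNA, TRNAGene, build_catalog, parse_annotation

__all__ = [
    "__version__",
    "RunConfig",
    "UniqueRead",
    "GenomeBundle",
    "SimulationConfig",
    "generate_genome",
    "simulate_reads",
    "classify_region",
    "main_region",
    "top_variants",
    "TRFRecord",
    "call_trfs",
    "MatureTRNA",
    "TRNAGene",
    "build_catalog",
    "parse_annotation",
]


def run_pipeline(config):
    """See :func:`trfscape.pipeline.run_pipeline` (imported lazily to keep
    the package import light)."""
    from .pipeline import run_pipeline as _run

    return _run(config)
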