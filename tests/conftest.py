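import numpy as np
import pytest
import scipy.sparse as sp

import scgerm
from scgerm.io import CellAnnotation, ExpressionMatrix

import pandas as pd


@pytest.fixture(scope="session")
def bundle() -> scgerm.SyntheticBundle:
    """Default synthetic world, seed 1 (shared across tests; treat as read-only)."""
    return scgerm.generate_bundle(scgerm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def report(bundle) -> scgerm.PipelineReport:
    """Full cascade run on the default bundle."""
    return scgerm.run_pipeline(
        bundle.variants,
        bundle.evidence,
        bundle.annotation,
        bundle.known_keys,
        bundle.bulk_keys,
        bundle.coverage,
        scgerm.MutationPipelineConfig(),
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 3 cells with hand-checkable counts."""
    counts = np.array([[1, 0, 2], [0, 0, 0], [3, 4, 0]])
    return ExpressionMatrix(["g1", "g2", "g3"], ["c1", "c2", "c3"], sp.csr_matrix(counts))


def make_annotation(cell_types: dict[str, str]) -> CellAnnotation:
    """Annotation from a barcode -> cell_type mapping (pseudotime omitted)."""
    return CellAnnotation(
        pd.DataFrame(
            {
                "barcode": list(cell_types),
                "cell_type": list(cell_types.values()),
                "pseudotime": np.nan,
                "is_somatic": [t in scgerm.SOMATIC_TYPES for t in cell_types.values()],
            }
        )
    )
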