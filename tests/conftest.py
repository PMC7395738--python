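import numpy as np
import pytest

from codegnet import ExpressionStudy, GeneSetLibrary, StudyCategory


def make_study(
    values,
    genes=None,
    n_case=None,
    study_id="S1",
    category=StudyCategory.CANCER_VS_NORMAL,
):
    """Build an ExpressionStudy from a genes x samples array; the first
    half of the columns (or ``n_case``) are cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i + 1}" for i in range(n_genes)]
    n_case = n_case if n_case is not None else n_samples // 2
    samples = [f"C{i + 1}" for i in range(n_case)] + [f"N{i + 1}" for i in range(n_samples - n_case)]
    return ExpressionStudy(
        study_id=study_id,
        genes=genes,
        samples=samples,
        values=values,
        case_samples=samples[:n_case],
        control_samples=samples[n_case:],
        category=category,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_library():
    return GeneSetLibrary(
        name="toy",
        terms={
            "TERM_A": {"A", "B", "C"},
            "TERM_B": {"C", "D", "E", "F"},
            "TERM_C": {"G", "H"},
        },
    )
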