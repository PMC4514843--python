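import numpy as np
import pandas as pd
import pytest

from polyapv import (
    AnalysisSettings,
    ExpressionMatrix,
    GeneClass,
    GeneClassSpec,
    NoiseSpec,
    SampleDesign,
    generate_experiment,
)


@pytest.fixture()
def settings():
    return AnalysisSettings()


def make_matrix(C, P, conditions, gene_ids=None):
    """Build an ExpressionMatrix from per-fraction arrays.

    C and P are (genes x samples) with samples ordered condition-major,
    replicate-minor; ``conditions`` labels each paired column.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    n = C.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(C.shape[0])]
    rows = []
    for frac, block in (("cytosolic", "cyto"), ("polysomal", "poly")):
        seen = {}
        for j, cond in enumerate(conditions):
            seen[cond] = seen.get(cond, 0) + 1
            rows.append({
                "sample_id": f"{block}_{cond}_r{seen[cond]}",
                "fraction": frac,
                "condition": cond,
                "replicate": seen[cond],
            })
    design = SampleDesign.from_frame(pd.DataFrame(rows))
    values = np.concatenate([C, P], axis=1)
    return ExpressionMatrix(gene_ids=np.array(gene_ids, dtype=object),
                            values=values, design=design)


@pytest.fixture()
def small_experiment():
    """A seeded 300-gene two-condition experiment with planted effects."""
    classes = [
        GeneClassSpec(GeneClass.TOP_REPRESSED, 30, delta_translation=-1.5),
        GeneClassSpec(GeneClass.ISG, 30, delta_cytosolic=1.0),
        GeneClassSpec(GeneClass.NULL, 240),
    ]
    noise = NoiseSpec()
    matrix, truth = generate_experiment(
        classes, noise, ["IFN", "IFN+Torin1"], n_replicates=4, seed=11
    )
    return matrix, truth
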