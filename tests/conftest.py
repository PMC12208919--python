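import numpy as np
import pandas as pd
import pytest

from clonalholes.model import AbundanceTable, SampleMeta


def make_table(counts, sample_specs, clone_keys=None):
    """Build an AbundanceTable from a plain count matrix.

    counts: 2-D list/array (clonotype x sample); sample_specs: list of
    (sample_id, group, subset) tuples or plain ids.
    """
    counts = np.asarray(counts)
    metas = []
    for i, spec in enumerate(sample_specs):
        if isinstance(spec, str):
            metas.append(SampleMeta(sample_id=spec))
        else:
            sid, group, subset = spec
            metas.append(SampleMeta(sample_id=sid, group=group, subset=subset,
                                    replicate=i + 1))
    if clone_keys is None:
        clone_keys = [
            (f"TRAV{i + 1}", f"TRAJ{i + 1}", f"CAA{i:03d}F")
            for i in range(counts.shape[0])
        ]
    index = pd.MultiIndex.from_tuples(
        clone_keys, names=["v_gene", "j_gene", "cdr3_aa"]
    )
    df = pd.DataFrame(counts, index=index, columns=[m.sample_id for m in metas])
    return AbundanceTable(df, metas)


@pytest.fixture
def two_group_table():
    """6 samples (3 control + 3 mutant), 5 clonotypes with mixed patterns."""
    counts = [
        [5, 4, 6, 3, 2, 4],  # shared everywhere
        [2, 1, 3, 0, 0, 0],  # control-exclusive, 3 samples -> dependent
        [0, 0, 0, 4, 2, 1],  # mutant-exclusive, 3 samples -> newcomer
        [1, 1, 0, 1, 0, 0],  # 3 of 6, both groups -> shared
        [1, 0, 0, 0, 0, 0],  # singleton presence -> not recurrent
    ]
    specs = [
        ("ctrl_1", "control", "M2"),
        ("ctrl_2", "control", "M2"),
        ("ctrl_3", "control", "M2"),
        ("mut_1", "mutant", "M2"),
        ("mut_2", "mutant", "M2"),
        ("mut_3", "mutant", "M2"),
    ]
    return make_table(counts, specs)
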