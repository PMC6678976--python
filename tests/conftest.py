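import numpy as np
import pytest

from gbmpanel import synth
from gbmpanel.types import (
    CountMatrix,
    ExprMatrix,
    ProbeClass,
    ProbeInfo,
    SampleAnnotation,
    ScaleTag,
)

RCC_FIXTURE = """<Header>
FileVersion,1.7
SoftwareVersion,4.0.0.3
</Header>

<Sample_Attributes>
ID,SAMPLE_1
Owner,core
</Sample_Attributes>

<Lane_Attributes>
ID,1
FovCount,555
</Lane_Attributes>

<Code_Summary>
CodeClass,Name,Accession,Count
Endogenous,EGFR,NM_005228.3,523
Endogenous,PDGFRA,NM_006206.4,88
Endogenous,VEGFA,NM_001025366.2,1204
Negative,NEG_A,ERCC_00096.1,4
Negative,NEG_B,ERCC_00041.1,9
Positive,POS_A,ERCC_00117.1,8012
Positive,POS_B,ERCC_00112.1,2104
</Code_Summary>
"""


@pytest.fixture
def rcc_file(tmp_path):
    path = tmp_path / "SAMPLE_1.rcc"
    path.write_text(RCC_FIXTURE)
    return path


@pytest.fixture
def small_counts():
    """3 endogenous + 2 housekeeping + 2 negative + 2 positive probes, 2 lanes."""
    probes = [
        ProbeInfo("EGFR", ProbeClass.ENDOGENOUS),
        ProbeInfo("PDGFRA", ProbeClass.ENDOGENOUS),
        ProbeInfo("VEGFA", ProbeClass.ENDOGENOUS),
        ProbeInfo("HK1", ProbeClass.HOUSEKEEPING),
        ProbeInfo("HK2", ProbeClass.HOUSEKEEPING),
        ProbeInfo("NEG_A", ProbeClass.NEGATIVE),
        ProbeInfo("NEG_B", ProbeClass.NEGATIVE),
        ProbeInfo("POS_A", ProbeClass.POSITIVE),
        ProbeInfo("POS_B", ProbeClass.POSITIVE),
    ]
    counts = np.array(
        [
            [100.0, 210.0],
            [50.0, 95.0],
            [400.0, 790.0],
            [300.0, 610.0],
            [250.0, 520.0],
            [4.0, 5.0],
            [16.0, 13.0],
            [800.0, 1650.0],
            [200.0, 390.0],
        ]
    )
    return CountMatrix(probes, counts, ["L1", "L2"])


@pytest.fixture
def labeled_small():
    data, truth = synth.make_labeled_dataset(
        synth.LabeledSpec(n_genes=60, n_samples=60, n_markers=6, effect=3.0, seed=7)
    )
    return data, truth


def expr_from_array(arr, genes=None, samples=None, scale=ScaleTag.LOG2):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExprMatrix(arr, genes=genes, samples=samples, scale_tag=scale)
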