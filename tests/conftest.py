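import pytest

from concord.data import CNCategory, CopyNumberDataset, Measurement, Tissue


def quant(pid, tissue, method, gene, value):
    return Measurement(
        patient_id=pid,
        tissue=Tissue(tissue),
        method_id=method,
        gene=gene,
        value_kind="quantitative",
        quant_value=float(value),
    )


def cat(pid, tissue, method, gene, call):
    return Measurement(
        patient_id=pid,
        tissue=Tissue(tissue),
        method_id=method,
        gene=gene,
        value_kind="categorical",
        call=CNCategory.parse(call),
    )


@pytest.fixture
def tiny_quant_dataset():
    """Two patients, one quantitative method, one gene, fully paired."""
    return CopyNumberDataset(
        [
            quant("P1", "tumor", "ddpcr", "CCND2", 3.1),
            quant("P1", "normal", "ddpcr", "CCND2", 2.0),
            quant("P2", "tumor", "ddpcr", "CCND2", 1.2),
            quant("P2", "normal", "ddpcr", "CCND2", 2.1),
        ]
    )
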