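import numpy as np
import pytest

from epiphase.calls import MoleculeCall
from epiphase.targets import TargetRegion


def make_target(sequence: str, target_id: str = "T", **kwargs) -> TargetRegion:
    defaults = dict(
        target_id=target_id,
        gene_id="G",
        chrom=target_id,
        start=0,
        end=len(sequence),
        strand="+",
        sequence=sequence,
    )
    defaults.update(kwargs)
    return TargetRegion(**defaults)


def make_call(calls, target_id="T", read_id="r0", sample="", replicate=""):
    return MoleculeCall(
        read_id=read_id,
        target_id=target_id,
        calls=np.asarray(calls, dtype=np.int8),
        sample=sample,
        replicate=replicate,
    )


@pytest.fixture
def small_target() -> TargetRegion:
    """~90 nt target with a handful of sites in every context."""
    seq = (
        "ACGTTACATTCGATTCAGTTACGTTCATTACGATCAGGTT"
        "ACGTAGGCCATTCGATAGCATGCCAGTTACCGGATTACGA"
    )
    return make_target(seq, "small")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240430)
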