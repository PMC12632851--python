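import dataclasses

import numpy as np
import pytest

from repeatweaver import (
    ABAPattern,
    ABASearchParams,
    NcRNATemplate,
    SimConfig,
    find_aba_patterns,
    generate_dataset,
)
from repeatweaver.workflow import derive_seed, random_reference

#: Template-loop segment with A=CAAU, B=GAUUC, A'=CAAU, encoding GAATCATTG.
LOOP_RNA = "CAAUGAUUCCAAU"


@pytest.fixture
def loop_template() -> NcRNATemplate:
    return NcRNATemplate(id="loop", sequence=LOOP_RNA)


@pytest.fixture
def whole_seq_params() -> ABASearchParams:
    return ABASearchParams(restrict_to_loop=False)


@pytest.fixture
def loop_pattern(loop_template, whole_seq_params) -> ABAPattern:
    return find_aba_patterns(loop_template, whole_seq_params)[0]


def make_datasets(seed: int, n_reads: int, sim_overrides=None):
    """WT + RT-dead read sets against a seeded random 3-kb reference."""
    template = NcRNATemplate(id="loop", sequence=LOOP_RNA)
    pattern = find_aba_patterns(template, ABASearchParams(restrict_to_loop=False))[0]
    reference = random_reference(derive_seed(seed, 0), 3000)
    base = SimConfig(**(sim_overrides or {}))
    wt = generate_dataset(
        template, pattern, reference,
        dataclasses.replace(base, seed=derive_seed(seed, 1)), n_reads, "WT",
    )
    ctrl = generate_dataset(
        None, None, reference,
        dataclasses.replace(base, seed=derive_seed(seed, 2)), n_reads, "RT_dead",
    )
    return template, pattern, reference, wt, ctrl


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
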