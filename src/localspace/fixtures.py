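"""Synthetic drug-like SMILES corpora and mock screeners.

The fragment grammar assembles molecules from aromatic/aliphatic ring cores,
short linkers and terminal substituents, restricted to atoms and bonds the
generator's 37-token alphabet can express (no stereo, no out-of-vocabulary
atoms, no multi-fragment strings).  It exists so every pipeline stage —
corpus building, training, sampling, screening — runs offline with
statistically reasonable input; it makes no claim of bioactivity realism.

Planted structure supports testing: exact-duplicate molecules (written as a
different random atom order), molecules whose canonical SMILES cannot be
tokenized (boron-containing), and homologous-series groups with very high
within-group and low between-group fingerprint similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_prep import (
    MoleculeRecord,
    SmilesCorpus,
    deduplicate,
    randomize_smiles,
    standardize,
)
from .screening import TanimotoScreener

__all__ = [
    "FixtureSpec",
    "generate_fixture_smiles",
    "generate_fixture_corpus",
    "make_two_group_fixture",
    "campaign_seed_set",
    "make_mock_screener",
    "tiny_config",
    "pretrain_tiny_generator",
    "MOCK_THRESHOLD",
    "TEST_TOKEN_BUDGET",
]

# ring cores as functions of (closure digit, substituent SMILES)
_CORES = [
    lambda d, s: f"c{d}ccc({s})cc{d}",      # benzene
    lambda d, s: f"c{d}ccc({s})nc{d}",      # pyridine
    lambda d, s: f"c{d}cnc({s})cn{d}",      # pyrazine
    lambda d, s: f"c{d}cc({s})cs{d}",       # thiophene
    lambda d, s: f"c{d}cc({s})c[nH]{d}",    # pyrrole
    lambda d, s: f"C{d}CCC({s})CC{d}",      # cyclohexane
    lambda d, s: f"C{d}CCN({s})CC{d}",      # piperidine
]

_LINKERS = ["C", "CC", "O", "N", "CN", "OC", "C(=O)", "C(=O)N", "NC(=O)", "CO"]

_TERMINALS = [
    "C", "CC", "CCC", "O", "OC", "OCC", "N", "NC", "F", "Cl", "Br",
    "C#N", "C(F)(F)F", "C(C)C", "C(=O)OC", "SC", "C(=O)N", "CCO",
]

_PREFIXES = ["", "C", "CC", "CCC", "OC", "NC(=O)", "CC(=O)", "N#C"]

#: valid molecules whose canonical SMILES contain boron, which the 37-token
#: alphabet cannot express — used to plant untokenizable corpus entries
_UNTOKENIZABLE = [
    "OB(O)c1ccccc1",
    "CB(O)O",
    "OB(O)c1ccc(C)cc1",
    "OB(O)c1ccncc1",
    "CCB(O)O",
    "OB(O)c1ccc(F)cc1",
    "OB(O)c1ccc(Cl)cc1",
    "OB(O)c1ccc(N)cc1",
    "OB(O)c1ccc(O)cc1",
    "OB(O)c1ccsc1",
]


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic corpus."""

    n_molecules: int = 100
    seed: int = 0
    n_duplicates: int = 0
    n_untokenizable: int = 0
    group_scaffolds: list[str] = field(default_factory=list)


def _grammar_molecule(rng: np.random.Generator) -> str:
    """One drug-like SMILES from the fragment grammar (depth <= 2)."""
    core = _CORES[rng.integers(len(_CORES))]
    if rng.random() < 0.5:  # nested second ring
        inner_core = _CORES[rng.integers(len(_CORES))]
        inner = inner_core(2, _TERMINALS[rng.integers(len(_TERMINALS))])
        sub = _LINKERS[rng.integers(len(_LINKERS))] + inner
    else:
        sub = (
            _LINKERS[rng.integers(len(_LINKERS))]
            + _TERMINALS[rng.integers(len(_TERMINALS))]
            if rng.random() < 0.5
            else _TERMINALS[rng.integers(len(_TERMINALS))]
        )
    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    return prefix + core(1, sub)


def generate_fixture_smiles(spec: FixtureSpec) -> list[str]:
    """Raw emitted SMILES, including any planted duplicates/untokenizables.

    The first ``n_molecules - n_duplicates - n_untokenizable`` entries are
    pairwise-distinct grammar molecules; planted duplicates rewrite earlier
    entries in a different random atom order; planted untokenizables are
    valid boron molecules outside the token alphabet.  Fully seeded.
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    n_base = spec.n_molecules - spec.n_duplicates - spec.n_untokenizable
    if n_base < 1:
        raise ValueError("planted entries exceed n_molecules")
    if spec.n_untokenizable > len(_UNTOKENIZABLE):
        raise ValueError(
            f"at most {len(_UNTOKENIZABLE)} untokenizable entries available"
        )
    rng = np.random.default_rng(spec.seed)
    base: list[str] = []
    seen: set[str] = set()
    while len(base) < n_base:
        smi = _grammar_molecule(rng)
        rec = standardize(smi)  # grammar output must always be valid
        if rec.smiles_canonical not in seen:
            seen.add(rec.smiles_canonical)
            base.append(rec.smiles_canonical)
    out = list(base)
    for j in range(spec.n_duplicates):
        src = base[int(rng.integers(len(base)))]
        variant = randomize_smiles(
            standardize(src), n_variants=1, seed=int(rng.integers(2**31 - 1))
        )[0]
        out.append(variant)
    out.extend(_UNTOKENIZABLE[: spec.n_untokenizable])
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def generate_fixture_corpus(spec: FixtureSpec) -> SmilesCorpus:
    """Standardized, deduplicated corpus over the raw emitted SMILES."""
    raw = generate_fixture_smiles(spec)
    records = deduplicate(
        [standardize(s, source_tag="training", id=str(i)) for i, s in enumerate(raw)]
    )
    return SmilesCorpus(records=records, sequences=raw, shuffle_seed=spec.seed)


def _homolog(unit: str, n: int, cap: str = "C") -> str:
    """Linear homologous chain: ``cap + unit * n``."""
    return cap + unit * n


def make_two_group_fixture(
    n_per_group: int = 5, seed: int = 0
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Two homologous series: near-identical within, dissimilar between.

    Group A are oligo-amide chain homologs (C/N/O atoms), group B are
    thioether chain homologs (C/S): interior repeat units contribute the
    same radius-3 environments, so within-group binary Tanimoto is close to
    1 while the disjoint heteroatom environments keep between-group
    similarity low.
    """
    group_a = [
        standardize(_homolog("NC(=O)C", n), source_tag="group_a", id=f"a{n}")
        for n in range(4, 4 + n_per_group)
    ]
    group_b = [
        standardize(_homolog("SCC", n, cap="CC"), source_tag="group_b", id=f"b{n}")
        for n in range(4, 4 + n_per_group)
    ]
    return group_a, group_b


def campaign_seed_set(
    seed: int = 0,
) -> tuple[MoleculeRecord, list[MoleculeRecord], MoleculeRecord]:
    """Seven seed molecules for the mock screening loop.

    Returns (active_like, six inactive_like, hidden_reference).  The hidden
    reference is a close homolog of the active-like seed (it is never shown
    to the generator), so a Tanimoto-to-reference scorer plays the role of
    the activity model: molecules from the active seed's neighborhood
    outscore the rest.
    """
    active = standardize(
        "CCOc1ccc(C(=O)NCc2ccc(F)cc2)cc1", source_tag="seed_active", id="active"
    )
    reference = standardize(
        "CCOc1ccc(C(=O)NCc2ccc(Cl)cc2)cc1", source_tag="reference", id="reference"
    )
    rng = np.random.default_rng(seed)
    inactives: list[MoleculeRecord] = []
    seen = {active.smiles_canonical, reference.smiles_canonical}
    while len(inactives) < 6:
        rec = standardize(
            _grammar_molecule(rng), source_tag="seed_inactive",
            id=f"inactive{len(inactives)}",
        )
        if rec.smiles_canonical not in seen:
            seen.add(rec.smiles_canonical)
            inactives.append(rec)
    return active, inactives, reference


def make_mock_screener(
    reference: MoleculeRecord, threshold: float = 0.0
) -> TanimotoScreener:
    """Deterministic similarity-to-reference screener/scorer."""
    return TanimotoScreener(reference=reference, threshold=threshold, name="mock")


# ---------------------------------------------------------------------------
# The scaled-down benchmark conditions used by the test suite and the
# reproduction script.  The full-scale protocol (128x64 batching, 256/512
# hidden units, 200,000-token sampling) is impractical for a quick offline
# check, so the same pipeline runs on a synthetic 200-molecule corpus with a
# 64-unit model, 8x16 batching and 2,000-token sampling budgets.

#: mock-screener pass threshold: Tanimoto to the hidden reference
MOCK_THRESHOLD = 0.2
#: pretraining conditions for the tiny benchmark generator
PRETRAIN_N_MOLECULES = 200
PRETRAIN_N_VARIANTS = 4
PRETRAIN_EPOCHS = 30
TEST_TOKEN_BUDGET = 2_000


def tiny_config(init_seed: int = 0, hidden_units: int = 64) -> "GeneratorConfig":
    """Scaled-down generator configuration for offline benchmarks."""
    from .generator import GeneratorConfig

    return GeneratorConfig(
        hidden_units=hidden_units, n_streams=8, chunk_len=16, init_seed=init_seed
    )


def pretrain_tiny_generator(seed: int = 0):
    """Pretrain the benchmark generator on the synthetic corpus.

    Mirrors the pretrain-on-a-generic-library stage at benchmark scale;
    takes tens of seconds on one CPU.
    """
    from .corpus import Vocabulary, build_stream
    from .generator import build_model

    corpus = generate_fixture_corpus(
        FixtureSpec(n_molecules=PRETRAIN_N_MOLECULES, seed=7)
    )
    sequences: list[str] = []
    for j, rec in enumerate(corpus.records):
        sequences.extend(randomize_smiles(rec, PRETRAIN_N_VARIANTS, seed=seed + j))
    stream = build_stream(sequences, Vocabulary(), shuffle_seed=seed)
    gen = build_model(tiny_config(init_seed=seed))
    gen.train(stream, PRETRAIN_EPOCHS, seed=seed)
    return gen
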