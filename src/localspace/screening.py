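"""The local-chemical-space virtual-screening loop and classifier metrics.

One round of the loop: randomize the seed molecules' SMILES, fine-tune the
pretrained generator on them (sampling periodically), pool and deduplicate
the sampled molecules, screen them, retain the top fraction by score, and
cluster the retained set into catalogs whose medoid centers seed the next
round.  Screening itself is pluggable: any object with ``classify`` (and
``score`` for ranking) can stand behind the pharmacophore/docking stage.
"""

from __future__ import annotations

import csv
import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit.Chem import Descriptors
from sklearn.metrics import roc_auc_score

from .chem_prep import MoleculeRecord, deduplicate, randomize_smiles
from .chemspace import ClusterAssignment, cluster_k, fingerprint, tanimoto
from .generator import Generator, SampleBatch

logger = logging.getLogger(__name__)

__all__ = [
    "Screener",
    "TanimotoScreener",
    "PropertyWindowScreener",
    "CommandScreener",
    "ClassifierEval",
    "ScreeningRound",
    "LoopConfig",
    "evaluate_classifier",
    "retain_top",
    "run_round",
    "run_campaign",
]


@runtime_checkable
class Screener(Protocol):
    """Pass/fail classifier with an optional real-valued score."""

    name: str

    def classify(self, record: MoleculeRecord) -> bool: ...

    def score(self, record: MoleculeRecord) -> float: ...


@dataclass
class TanimotoScreener:
    """Similarity-to-reference screener: pass iff Tanimoto >= threshold.

    The score is the radius-3 circular-fingerprint Tanimoto similarity to
    the reference molecule, so ranking favors the reference's neighborhood.
    """

    reference: MoleculeRecord
    threshold: float = 0.0
    name: str = "tanimoto-reference"

    def __post_init__(self):
        self._ref_fp = fingerprint(self.reference)

    def score(self, record: MoleculeRecord) -> float:
        return tanimoto(fingerprint(record), self._ref_fp)

    def classify(self, record: MoleculeRecord) -> bool:
        return self.score(record) >= self.threshold


@dataclass
class PropertyWindowScreener:
    """Descriptor-window screener: pass iff every descriptor is in range.

    ``windows`` maps an RDKit descriptor name (e.g. "MolWt", "MolLogP",
    "TPSA") to an inclusive (low, high) window.  The score is the number of
    satisfied windows (useful only for coarse ranking).
    """

    windows: dict[str, tuple[float, float]]
    name: str = "property-window"

    def _values(self, record: MoleculeRecord) -> dict[str, float]:
        mol = record.mol()
        return {k: getattr(Descriptors, k)(mol) for k in self.windows}

    def classify(self, record: MoleculeRecord) -> bool:
        vals = self._values(record)
        return all(lo <= vals[k] <= hi for k, (lo, hi) in self.windows.items())

    def score(self, record: MoleculeRecord) -> float:
        vals = self._values(record)
        return float(
            sum(lo <= vals[k] <= hi for k, (lo, hi) in self.windows.items())
        )


@dataclass
class CommandScreener:
    """Shell out to any external scorer reading/writing smiles,id,score CSV.

    The command is run once per batch with the input CSV path appended; it
    must print an output CSV with columns smiles,id,score to stdout or write
    it to the path given as its second argument.
    """

    command: list[str]
    threshold: float = 0.0
    name: str = "external-command"

    def score_batch(self, records: Sequence[MoleculeRecord]) -> dict[str, float]:
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.csv"
            out = Path(tmp) / "out.csv"
            with open(inp, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["smiles", "id"])
                for r in records:
                    w.writerow([r.smiles_canonical, r.id])
            proc = subprocess.run(
                [*self.command, str(inp), str(out)],
                capture_output=True, text=True, check=True,
            )
            text = out.read_text() if out.exists() else proc.stdout
            scores: dict[str, float] = {}
            for row in csv.DictReader(text.splitlines()):
                scores[row["smiles"]] = float(row["score"])
        return scores

    def score(self, record: MoleculeRecord) -> float:
        return self.score_batch([record])[record.smiles_canonical]

    def classify(self, record: MoleculeRecord) -> bool:
        return self.score(record) >= self.threshold


@dataclass(frozen=True)
class ClassifierEval:
    """Confusion counts plus specificity, sensitivity and rank AUC."""

    true_positive: int
    true_negative: int
    false_positive: int
    false_negative: int
    specificity: float
    sensitivity: float
    auc: float | None


def evaluate_classifier(
    screener: Screener,
    actives: Sequence[MoleculeRecord],
    inactives: Sequence[MoleculeRecord],
    compute_auc: bool = True,
) -> ClassifierEval:
    """Confusion counts from ``classify``; AUC rank-wise from ``score``.

    specificity = TN / (TN + FP); sensitivity = TP / (TP + FN).  The AUC is
    the probability that a random active outscores a random inactive, ties
    counted one half.
    """
    if not actives or not inactives:
        raise ValueError("actives and inactives must both be non-empty")
    overlap = {a.smiles_canonical for a in actives} & {
        i.smiles_canonical for i in inactives
    }
    if overlap:
        raise ValueError(f"actives and inactives overlap: {sorted(overlap)[:3]}")
    tp = sum(screener.classify(a) for a in actives)
    fn = len(actives) - tp
    fp = sum(screener.classify(i) for i in inactives)
    tn = len(inactives) - fp
    auc = None
    if compute_auc:
        if not hasattr(screener, "score"):
            raise ValueError("screener has no score(); cannot compute AUC")
        y = [1] * len(actives) + [0] * len(inactives)
        s = [screener.score(m) for m in [*actives, *inactives]]
        auc = float(roc_auc_score(y, s))
    return ClassifierEval(
        true_positive=tp,
        true_negative=tn,
        false_positive=fp,
        false_negative=fn,
        specificity=tn / (tn + fp),
        sensitivity=tp / (tp + fn),
        auc=auc,
    )


def retain_top(
    passing: Sequence[tuple[MoleculeRecord, float]], retain_fraction: float = 0.5
) -> list[tuple[MoleculeRecord, float]]:
    """Keep the first ceil(fraction * n) molecules sorted by score.

    The sort is stable and descending, so equal scores keep input order.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise ValueError("retain_fraction must be in (0, 1]")
    if not passing:
        logger.warning("retain_top called with no scored molecules")
        return []
    order = sorted(range(len(passing)), key=lambda i: -passing[i][1])
    n_keep = math.ceil(retain_fraction * len(passing))
    return [passing[i] for i in order[:n_keep]]


@dataclass
class LoopConfig:
    """Knobs for one generate-and-screen campaign.

    Protocol defaults: 30 fine-tuning epochs in round 1 and 20 in later
    rounds, sampling every 10 epochs with a 200,000-token budget each time;
    top 50% of scored passers retained; 7 cluster catalogs.
    """

    epochs_round1: int = 30
    epochs_later: int = 20
    sample_every: int = 10
    tokens_per_sample: int = 200_000
    retain_fraction: float = 0.5
    k_clusters: int = 7
    n_variants: int = 10
    seed: int = 0


@dataclass
class ScreeningRound:
    """Everything one cycle of the loop produced."""

    round_index: int
    seed_molecules: list[MoleculeRecord]
    generated_pool: list[MoleculeRecord]
    passing: list[MoleculeRecord]
    retained: list[tuple[MoleculeRecord, float]]
    clusters: ClusterAssignment | None
    centers: list[MoleculeRecord]
    sample_batches: list[SampleBatch] = field(default_factory=list)

    @property
    def retained_records(self) -> list[MoleculeRecord]:
        return [r for r, _ in self.retained]


def _pool_batches(batches: Sequence[SampleBatch]) -> list[MoleculeRecord]:
    pooled: list[MoleculeRecord] = []
    for b in batches:
        pooled.extend(b.valid_unique)
    return deduplicate(pooled)


def run_round(
    generator: Generator,
    seed_molecules: Sequence[MoleculeRecord],
    screeners: Sequence[Screener],
    config: LoopConfig,
    round_index: int = 1,
    scorer: Screener | None = None,
) -> ScreeningRound:
    """One cycle: fine-tune on seeds, sample, screen, retain, cluster.

    ``scorer`` defaults to the last screener.  A molecule passes iff every
    screener passes it.  With zero passers the round ends with an empty
    retained set and no clustering.
    """
    seed_molecules = list(seed_molecules)
    scorer = scorer if scorer is not None else screeners[-1]
    rseed = config.seed + 1000 * round_index

    sequences: list[str] = []
    for j, rec in enumerate(seed_molecules):
        sequences.extend(randomize_smiles(rec, config.n_variants, seed=rseed + j))

    n_epochs = config.epochs_round1 if round_index == 1 else config.epochs_later
    batches = generator.fine_tune(
        sequences,
        n_epochs=n_epochs,
        sample_every=config.sample_every,
        tokens_per_sample=config.tokens_per_sample,
        seed=rseed,
    )
    pool = _pool_batches(batches)
    passing = [m for m in pool if all(s.classify(m) for s in screeners)]
    logger.info(
        "round %d: %d unique generated, %d passing", round_index, len(pool),
        len(passing),
    )
    if not passing:
        logger.warning("round %d: no molecules passed the screeners", round_index)
        return ScreeningRound(
            round_index, seed_molecules, pool, [], [], None, [], batches
        )
    scored = [(m, float(scorer.score(m))) for m in passing]
    retained = retain_top(scored, config.retain_fraction)
    retained_records = [m for m, _ in retained]

    k = min(config.k_clusters, len(retained_records))
    if k < config.k_clusters:
        logger.warning(
            "round %d: only %d retained molecules; clustering with k=%d",
            round_index, len(retained_records), k,
        )
    clusters = cluster_k(retained_records, k=k, seed=rseed)
    return ScreeningRound(
        round_index=round_index,
        seed_molecules=seed_molecules,
        generated_pool=pool,
        passing=passing,
        retained=retained,
        clusters=clusters,
        centers=clusters.centers,
        sample_batches=batches,
    )


def run_campaign(
    generator: Generator,
    seed_molecules: Sequence[MoleculeRecord],
    screeners: Sequence[Screener],
    n_rounds: int = 2,
    config: LoopConfig | None = None,
    scorer: Screener | None = None,
) -> list[ScreeningRound]:
    """Chain rounds; each round is seeded by the previous round's centers.

    The campaign halts early (with the partial history) if a round retains
    nothing.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    config = config or LoopConfig()
    rounds: list[ScreeningRound] = []
    seeds = list(seed_molecules)
    for r in range(1, n_rounds + 1):
        rnd = run_round(generator, seeds, screeners, config, round_index=r,
                        scorer=scorer)
        rounds.append(rnd)
        if not rnd.retained:
            logger.warning("campaign halted after round %d: nothing retained", r)
            break
        if len(rnd.centers) < config.k_clusters:
            logger.warning(
                "round %d produced %d cluster centers (< %d); using all of them",
                r, len(rnd.centers), config.k_clusters,
            )
        seeds = rnd.centers
    return rounds


def nearest_seed_attribution(
    retained: Sequence[MoleculeRecord], seeds: Sequence[MoleculeRecord]
) -> list[int]:
    """Index of the most similar seed (circular-r3 Tanimoto) per molecule."""
    seed_fps = [fingerprint(s) for s in seeds]
    out = []
    for m in retained:
        fp = fingerprint(m)
        sims = [tanimoto(fp, sfp) for sfp in seed_fps]
        out.append(int(np.argmax(sims)))
    return out
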