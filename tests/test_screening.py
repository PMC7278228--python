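"""Classifier evaluation, retention filter and the screening loop."""

import math
import sys

import numpy as np
import pytest

from localspace.chem_prep import MoleculeRecord, standardize
from localspace.fixtures import make_mock_screener
from localspace.screening import (
    CommandScreener,
    LoopConfig,
    PropertyWindowScreener,
    TanimotoScreener,
    evaluate_classifier,
    nearest_seed_attribution,
    retain_top,
    run_campaign,
    run_round,
)


class _ConstantScreener:
    name = "constant"

    def __init__(self, passes=True, scores=None):
        self._passes = passes
        self._scores = scores or {}

    def classify(self, record):
        return self._passes

    def score(self, record):
        return self._scores.get(record.smiles_canonical, 0.0)


def _mols(smiles):
    return [standardize(s, id=str(i)) for i, s in enumerate(smiles)]


ACTIVES = ["CCO", "CCN", "CCC", "CCOC", "CC(C)O", "CCCO", "CC(C)N",
           "CCCN", "CCCC", "CCCCO"]
INACTIVES = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "Cc1ccccc1",
             "Nc1ccccc1", "Oc1ccccc1", "Clc1ccccc1", "Brc1ccccc1",
             "Fc1ccccc1"]


class TestEvaluateClassifier:
    def test_pass_everything(self):
        ev = evaluate_classifier(
            _ConstantScreener(True), _mols(ACTIVES), _mols(INACTIVES),
            compute_auc=False,
        )
        assert ev.sensitivity == 1.0 and ev.specificity == 0.0

    def test_specificity_formula(self):
        # 3 inactives rejected, 1 wrongly passed -> specificity 0.75
        screener = TanimotoScreener(standardize("Cc1ccccc1"), threshold=0.2)
        actives, inactives = _mols(["Cc1ccccc1"]), _mols(INACTIVES[:4])
        flags = [screener.classify(m) for m in inactives]
        assert sum(flags) == 1  # precondition: exactly one confounder
        ev = evaluate_classifier(screener, actives, inactives, compute_auc=False)
        assert ev.true_negative == 3 and ev.false_positive == 1
        assert ev.specificity == 0.75

    def test_counts_sum_to_n(self):
        ev = evaluate_classifier(
            _ConstantScreener(True), _mols(ACTIVES), _mols(INACTIVES),
            compute_auc=False,
        )
        total = (ev.true_positive + ev.true_negative
                 + ev.false_positive + ev.false_negative)
        assert total == 20

    def test_perfectly_separating_scores_give_auc_one(self):
        scores = {standardize(s).smiles_canonical: 10.0 + i
                  for i, s in enumerate(ACTIVES)}
        scores.update({standardize(s).smiles_canonical: float(i)
                       for i, s in enumerate(INACTIVES)})
        ev = evaluate_classifier(
            _ConstantScreener(True, scores), _mols(ACTIVES), _mols(INACTIVES)
        )
        assert ev.auc == 1.0

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        actives, inactives = _mols(ACTIVES), _mols(INACTIVES)
        scores = {m.smiles_canonical: float(rng.integers(0, 5))
                  for m in actives + inactives}
        ev = evaluate_classifier(
            _ConstantScreener(True, scores), actives, inactives
        )
        wins = 0.0  # oracle: exhaustive pair enumeration, ties count 1/2
        for a in actives:
            for i in inactives:
                sa, si = scores[a.smiles_canonical], scores[i.smiles_canonical]
                wins += 1.0 if sa > si else (0.5 if sa == si else 0.0)
        assert ev.auc == pytest.approx(wins / (len(actives) * len(inactives)))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            evaluate_classifier(
                _ConstantScreener(True), _mols(["CCO"]), _mols(["OCC"])
            )


class TestRetainTop:
    def test_keeps_highest_scored_half(self):
        scored = [(MoleculeRecord(f"C{'C' * i}O", id=str(i)), float(i))
                  for i in range(10)]
        kept = retain_top(scored, 0.5)
        assert len(kept) == 5
        assert [m.id for m, _ in kept] == ["9", "8", "7", "6", "5"]

    def test_ceil_on_odd_counts(self):
        scored = [(MoleculeRecord("CCO", id=str(i)), float(i)) for i in range(7)]
        assert len(retain_top(scored, 0.5)) == math.ceil(3.5)

    def test_single_molecule_survives(self):
        assert len(retain_top([(MoleculeRecord("CCO"), 1.0)], 0.5)) == 1

    def test_ties_keep_input_order(self):
        scored = [(MoleculeRecord("CCO", id=str(i)), 1.0) for i in range(4)]
        assert [m.id for m, _ in retain_top(scored, 0.5)] == ["0", "1"]

    def test_empty_input(self):
        assert retain_top([], 0.5) == []

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            retain_top([(MoleculeRecord("CCO"), 1.0)], 0.0)


class TestScreeners:
    def test_reference_scores_itself_one(self):
        ref = standardize("CC(=O)Nc1ccc(O)cc1")
        screener = make_mock_screener(ref, threshold=0.5)
        assert screener.classify(ref) and screener.score(ref) == 1.0

    def test_zero_threshold_passes_everything(self, fixture_corpus):
        screener = make_mock_screener(standardize("CCO"), threshold=0.0)
        assert all(screener.classify(m) for m in fixture_corpus[:10])

    def test_property_window(self):
        screener = PropertyWindowScreener({"MolWt": (100.0, 300.0)})
        assert screener.classify(standardize("CC(=O)Nc1ccc(O)cc1"))  # 151 Da
        assert not screener.classify(standardize("CCO"))  # 46 Da

    def test_command_screener_round_trip(self, tmp_path):
        scorer = tmp_path / "scorer.py"
        scorer.write_text(
            "import csv, sys\n"
            "rows = list(csv.DictReader(open(sys.argv[1])))\n"
            "with open(sys.argv[2], 'w', newline='') as fh:\n"
            "    w = csv.writer(fh); w.writerow(['smiles', 'id', 'score'])\n"
            "    for r in rows:\n"
            "        w.writerow([r['smiles'], r['id'], len(r['smiles'])])\n"
        )
        screener = CommandScreener([sys.executable, str(scorer)], threshold=4.0)
        assert screener.score(standardize("CCOCC")) == 5.0
        assert screener.classify(standardize("CCOCC"))
        assert not screener.classify(standardize("CCO"))


@pytest.fixture(scope="module")
def mock_round(tiny_pretrained, campaign_setup):
    active, inactives, reference = campaign_setup
    screener = make_mock_screener(reference, threshold=0.2)
    gen = tiny_pretrained.clone()
    rnd = run_round(
        gen, [active, *inactives], [screener],
        LoopConfig(tokens_per_sample=2000, seed=1),
    )
    return rnd


class TestRunRound:
    def test_structural_invariants(self, mock_round):
        pool = {m.smiles_canonical for m in mock_round.generated_pool}
        passing = {m.smiles_canonical for m in mock_round.passing}
        retained = {m.smiles_canonical for m in mock_round.retained_records}
        assert retained <= passing <= pool

    def test_retained_count_is_ceil_of_fraction(self, mock_round):
        assert len(mock_round.retained) == math.ceil(0.5 * len(mock_round.passing))

    def test_centers_are_medoids_of_retained(self, mock_round):
        retained = {m.smiles_canonical for m in mock_round.retained_records}
        assert mock_round.centers
        assert all(c.smiles_canonical in retained for c in mock_round.centers)

    def test_pool_is_deduplicated(self, mock_round):
        smiles = [m.smiles_canonical for m in mock_round.generated_pool]
        assert len(smiles) == len(set(smiles))


class TestRunCampaign:
    def test_single_round_equals_run_round(
        self, tiny_pretrained, campaign_setup, mock_round
    ):
        active, inactives, reference = campaign_setup
        screener = make_mock_screener(reference, threshold=0.2)
        rounds = run_campaign(
            tiny_pretrained.clone(), [active, *inactives], [screener],
            n_rounds=1, config=LoopConfig(tokens_per_sample=2000, seed=1),
        )
        assert len(rounds) == 1
        assert ([m.smiles_canonical for m in rounds[0].retained_records]
                == [m.smiles_canonical for m in mock_round.retained_records])

    def test_round2_seeded_by_round1_centers(
        self, tiny_pretrained, campaign_setup
    ):
        active, inactives, reference = campaign_setup
        screener = make_mock_screener(reference, threshold=0.2)
        rounds = run_campaign(
            tiny_pretrained.clone(), [active, *inactives], [screener],
            n_rounds=2, config=LoopConfig(tokens_per_sample=2000, seed=5),
        )
        assert len(rounds) == 2
        assert ([m.smiles_canonical for m in rounds[1].seed_molecules]
                == [m.smiles_canonical for m in rounds[0].centers])

    def test_reproducible_under_fixed_seeds(self, tiny_pretrained, campaign_setup):
        active, inactives, reference = campaign_setup
        screener = make_mock_screener(reference, threshold=0.2)
        outcomes = []
        for _ in range(2):
            rounds = run_campaign(
                tiny_pretrained.clone(), [active, *inactives], [screener],
                n_rounds=2, config=LoopConfig(tokens_per_sample=1000, seed=2),
            )
            outcomes.append(
                [[m.smiles_canonical for m in rnd.retained_records]
                 for rnd in rounds]
            )
        assert outcomes[0] == outcomes[1]

    def test_nothing_passing_halts_with_diagnostic(
        self, tiny_pretrained, campaign_setup
    ):
        active, inactives, reference = campaign_setup
        impossible = make_mock_screener(reference, threshold=1.01)
        rounds = run_campaign(
            tiny_pretrained.clone(), [active, *inactives], [impossible],
            n_rounds=2, config=LoopConfig(tokens_per_sample=500, seed=0),
        )
        assert len(rounds) == 1
        assert rounds[0].retained == [] and rounds[0].clusters is None


class TestNearestSeedAttribution:
    def test_seed_attributes_to_itself(self, campaign_setup):
        active, inactives, _ = campaign_setup
        seeds = [active, *inactives]
        assert nearest_seed_attribution([active], seeds) == [0]
        assert nearest_seed_attribution([inactives[2]], seeds) == [3]
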