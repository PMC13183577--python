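import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tspforage.measures import compute_measures, parse_event_log, write_event_log
from tspforage.morphology import (
    MorphClass,
    classify_cell,
    count_processes,
    shape_descriptors,
)
from tspforage.simulate import (
    AgentParams,
    MicrogliaMixture,
    default_design,
    make_cell_mask,
    simulate_cohort,
    simulate_microglia,
    simulate_trial,
)

PURE_OPTIMAL = AgentParams(
    strategy_weights={"OPTIMAL": 1.0, "NN": 0.0, "HULL": 0.0, "RANDOM": 0.0},
    softmax_temperature=0.0, p_skip=0.0, memory_capacity=None,
)


class TestAgentParams:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AgentParams(strategy_weights={"OPTIMAL": 0.5, "NN": 0.2,
                                          "HULL": 0.0, "RANDOM": 0.0})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="p_skip"):
            AgentParams(p_skip=1.5)
        with pytest.raises(ValueError, match="temperature"):
            AgentParams(softmax_temperature=-1)


class TestSimulateTrial:
    def test_pure_optimal_agent_identities(self, configs, opts_by_id):
        """A noiseless optimal-route follower scores PAO 0, full optimality
        fractions and a clean memory record on every bundled layout."""
        for cfg in configs:
            opt = opts_by_id[cfg.config_id]
            for seed in range(3):
                m = compute_measures(
                    simulate_trial(PURE_OPTIMAL, cfg, opt, seed), cfg, opt
                )
                assert m.pao_diff == pytest.approx(0.0, abs=1e-9)
                assert m.prop_opt == 1.0
                assert m.prop_dist_opt == 1.0
                assert m.revisits == 0
                assert m.skips == 0
                assert m.span == cfg.n_targets

    def test_skip_process_matches_geometric_expectation(
        self, configs_by_id, opts_by_id
    ):
        """Retrieval failures are Bernoulli per contact, so failures per
        target are geometric: E = n * p/(1-p).  The scored skip count is
        slightly below that because consecutive re-contacts of the last
        remaining target collapse into one visit bout."""
        cfg, opt = configs_by_id[8], opts_by_id[8]
        p = 0.15
        params = AgentParams(
            strategy_weights=PURE_OPTIMAL.strategy_weights,
            softmax_temperature=0.0, p_skip=p, memory_capacity=None,
        )
        rng = np.random.default_rng(42)
        n = cfg.n_targets
        N = 3000
        skips = np.empty(N)
        for i in range(N):
            m = compute_measures(simulate_trial(params, cfg, opt, rng), cfg, opt)
            skips[i] = m.skips
        exact = n * p / (1 - p)
        collapse_corrected = (n - 1) * p / (1 - p) + p
        se = np.sqrt(n * p / (1 - p) ** 2 / N)
        assert skips.mean() <= exact + 3 * se
        assert skips.mean() == pytest.approx(collapse_corrected,
                                             abs=3 * se + 0.05)

    def test_zero_capacity_produces_revisits(self, configs_by_id, opts_by_id):
        """With no memory the depleted targets re-enter the candidate set
        and revisits occur on essentially every large trial."""
        cfg, opt = configs_by_id[8], opts_by_id[8]
        params = AgentParams(
            strategy_weights={"OPTIMAL": 0.0, "NN": 0.7, "HULL": 0.0,
                              "RANDOM": 0.3},
            softmax_temperature=0.5, p_skip=0.0, memory_capacity=0,
        )
        rng = np.random.default_rng(1)
        revisits = [
            compute_measures(simulate_trial(params, cfg, opt, rng), cfg,
                             opt).revisits
            for _ in range(20)
        ]
        assert np.mean([r > 0 for r in revisits]) >= 0.9

    def test_lapse_rate_produces_revisits_and_zero_is_clean(
        self, configs_by_id, opts_by_id
    ):
        cfg, opt = configs_by_id[6], opts_by_id[6]
        noisy = AgentParams(
            strategy_weights=PURE_OPTIMAL.strategy_weights,
            p_lapse=0.2, memory_capacity=None,
        )
        rng = np.random.default_rng(3)
        rev = [
            compute_measures(simulate_trial(noisy, cfg, opt, rng), cfg,
                             opt).revisits
            for _ in range(30)
        ]
        assert np.mean(rev) > 0.5

    def test_velocity_reflects_speed_parameter(self, configs_by_id, opts_by_id):
        cfg, opt = configs_by_id[3], opts_by_id[3]
        params = AgentParams(
            strategy_weights=PURE_OPTIMAL.strategy_weights,
            speed_mean=25.0, speed_sd=0.0,
        )
        m = compute_measures(simulate_trial(params, cfg, opt, 0), cfg, opt)
        assert m.velocity == pytest.approx(25.0, rel=1e-6)

    def test_step_cap_raises_on_livelock(self, configs_by_id, opts_by_id):
        """Deterministic greedy with zero memory can oscillate between two
        depleted targets forever; the guard refuses instead of hanging."""
        cfg, opt = configs_by_id[8], opts_by_id[8]
        params = AgentParams(
            strategy_weights={"OPTIMAL": 0.0, "NN": 1.0, "HULL": 0.0,
                              "RANDOM": 0.0},
            softmax_temperature=0.0, p_skip=0.0, memory_capacity=0,
        )
        raised = False
        for seed in range(10):
            try:
                simulate_trial(params, cfg, opt, seed)
            except RuntimeError:
                raised = True
                break
        assert raised


class TestSimulateCohort:
    def test_deterministic_given_seed(self, configs):
        design = default_design(configs, n_per_cell=2)
        a = simulate_cohort(design, 7)
        b = simulate_cohort(design, 7)
        assert len(a.logs) == len(b.logs) == 4 * 2 * len(configs)
        for la, lb in zip(a.logs, b.logs):
            assert la.events == lb.events
            assert np.array_equal(la.track, lb.track)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_generated_events_pass_the_parser(self, tmp_path, configs):
        design = default_design(configs, n_per_cell=2)
        cohort = simulate_cohort(design, 3)
        path = tmp_path / "events.csv"
        write_event_log(cohort.logs, path)
        logs = parse_event_log(path)
        assert len(logs) == len(cohort.logs)

    def test_adherence_weight_recovered_by_regression(
        self, configs, configs_by_id, opts_by_id
    ):
        """Across agents spanning a range of OPTIMAL weights, measured
        prop_opt regresses on the generating weight with a clearly positive
        slope (36 agents, as in the study cohort)."""
        from tspforage.simulate import _weights

        rng = np.random.default_rng(0)
        weights = np.linspace(0.1, 0.9, 36)
        xs, ys = [], []
        for i, w in enumerate(weights):
            params = AgentParams(
                strategy_weights=_weights(float(w)),
                softmax_temperature=0.3, p_lapse=0.06, speed_sd=2.0,
            )
            ms = []
            for cfg in configs:
                if cfg.config_id in (1, 2):
                    continue
                opt = opts_by_id[cfg.config_id]
                lg = simulate_trial(params, cfg, opt, rng)
                ms.append(compute_measures(lg, cfg, opt))
            xs.append(w)
            ys.append(np.mean([m.prop_opt for m in ms]))
        res = sps.linregress(xs, ys)
        assert res.slope > 0
        assert res.pvalue < 0.001


class TestSimulateMicroglia:
    def test_single_cells_round_trip(self):
        rng = np.random.default_rng(5)
        for morph in MorphClass:
            mask = make_cell_mask(morph, rng, noise=0.0)
            _, _, circ = shape_descriptors(mask)
            n_proc = count_processes(mask)
            assert classify_cell(circ, n_proc) is morph

    def test_mixture_recovery_and_metadata_alignment(self):
        mix = {("SHR", "F", "DG"): MicrogliaMixture(0.3, 0.3, 0.4)}
        rats = {("SHR", "F"): ["r1", "r2"]}
        masks, meta = simulate_microglia(mix, rats, n_cells=40, noise=0.0,
                                         seed=9)
        assert len(masks) == len(meta) == 80
        correct = 0
        for mask, row in zip(masks, meta.itertuples()):
            _, _, circ = shape_descriptors(mask)
            pred = classify_cell(circ, count_processes(mask))
            correct += pred.value == row.true_class
        assert correct == len(masks)
        frac_hyp = (meta["true_class"] == "HYPERTROPHIC").mean()
        lo, hi = sps.binom.interval(0.999, len(meta), 0.4)
        assert lo / len(meta) <= frac_hyp <= hi / len(meta)

    def test_accuracy_degrades_with_noise(self):
        """Average classification accuracy is non-increasing as boundary
        noise grows (up to Monte-Carlo slack)."""
        mix = {("SHR", "F", "DG"): MicrogliaMixture(1 / 3, 1 / 3, 1 / 3)}
        rats = {("SHR", "F"): ["r1"]}
        accs = []
        for noise in (0.0, 1.0, 3.0):
            masks, meta = simulate_microglia(mix, rats, n_cells=60,
                                             noise=noise, seed=31)
            ok = 0
            for mask, row in zip(masks, meta.itertuples()):
                _, _, circ = shape_descriptors(mask)
                pred = classify_cell(circ, count_processes(mask))
                ok += pred.value == row.true_class
            accs.append(ok / len(masks))
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] - 0.05
        assert accs[1] >= accs[2] - 0.05
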