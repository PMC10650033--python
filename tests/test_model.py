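"""Rate arithmetic, cell-state algebra and the transition structure."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from intrares import (
    CellState,
    DrugClass,
    Gene,
    INHIBITOR_FOR,
    ModelParams,
    SENSITIZING_GENES,
    death_probability,
    division_probability,
    enumerate_transitions,
    is_resistant,
    rate_triple,
    split_division,
    total_transition_rate,
)

# The nine per-gene sensitization probabilities and the shared
# point-mutation probability for resistance, summed by hand as the oracle
# for the no-driver cell's total transition rate.
TABLE_MU_SENS = [3.15e-5, 2.43e-5, 1.08e-5, 1.35e-5, 1.80e-5, 1.35e-5, 1.80e-5, 1.89e-5, 0.90e-5]
MU_RES = 1e-8


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "s, b", [(0.0, 0.5), (0.05, 0.525), (0.005, 0.5025)]
    )
    def test_division_probability(self, s, b):
        assert division_probability(s) == pytest.approx(b, abs=1e-15)

    @pytest.mark.parametrize("b, d", [(0.5, 0.5), (0.525, 0.475), (0.5025, 0.4975)])
    def test_death_probability(self, b, d):
        assert death_probability(b) == pytest.approx(d, abs=1e-15)

    @pytest.mark.parametrize(
        "b, u, expected",
        [
            (0.525, 0.0, (0.525, 0.0)),
            (0.525, 1e-5, (0.52499475, 5.25e-6)),
            (0.5, 0.5, (0.25, 0.25)),
        ],
    )
    def test_split_division(self, b, u, expected):
        b_sync, b_async = split_division(b, u)
        assert b_sync == pytest.approx(expected[0], rel=1e-12)
        assert b_async == pytest.approx(expected[1], rel=1e-12)

    @pytest.mark.parametrize("bad_s", [-0.1, 1.0, 1.5])
    def test_selection_advantage_domain(self, bad_s):
        with pytest.raises(ValueError):
            division_probability(bad_s)

    def test_split_rejects_u_at_one(self):
        with pytest.raises(ValueError):
            split_division(0.525, 1.0)

    @given(
        s=st.floats(0.0, 0.999), u=st.floats(0.0, 0.999, exclude_max=False)
    )
    def test_rate_identities(self, s, u):
        """b + d = 1 and b_sync + b_async = b hold across the whole domain."""
        t = rate_triple(s, u)
        assert t.b + t.d == pytest.approx(1.0, abs=1e-12)
        assert t.b_sync + t.b_async == pytest.approx(t.b, abs=1e-12)
        assert 0.0 <= t.b_async <= t.b <= 1.0


class TestCellState:
    def test_zero_counts_dropped_for_sparse_keys(self):
        a = CellState(gene=Gene.EGFR, resistance={DrugClass.PT: 0})
        b = CellState(gene=Gene.EGFR)
        assert a == b and hash(a) == hash(b)

    def test_canonical_order_independent_of_input_order(self):
        a = CellState(resistance={DrugClass.PT: 1, DrugClass.EGFRI: 2})
        b = CellState(resistance={DrugClass.EGFRI: 2, DrugClass.PT: 1})
        assert a == b

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            CellState(resistance={DrugClass.PT: -1})

    def test_xor_gate_blocks_second_sensitization(self):
        cell = CellState().with_sensitization(Gene.EGFR)
        assert cell.gene is Gene.EGFR
        with pytest.raises(ValueError):
            cell.with_sensitization(Gene.KRAS)

    def test_resistance_increment(self):
        cell = CellState().with_extra_resistance(DrugClass.PT)
        assert cell.resistance_count(DrugClass.PT) == 1
        assert cell.with_extra_resistance(DrugClass.PT).resistance_count(DrugClass.PT) == 2

    @pytest.mark.parametrize(
        "state, expected",
        [
            (CellState(), False),
            (CellState(gene=Gene.EGFR, resistance={DrugClass.PT: 1}), True),
            (CellState(resistance={DrugClass.PT: 0}), False),
        ],
    )
    def test_is_resistant(self, state, expected):
        assert is_resistant(state) is expected


class TestTransitions:
    def test_untyped_cell_has_nine_sensitizations_plus_platinum(self, params):
        trans = enumerate_transitions(CellState(), params)
        assert len(trans) == 10
        genes = {t.target.gene for t in trans if t.target.gene is not Gene.NONE}
        assert genes == set(SENSITIZING_GENES)
        u = total_transition_rate(CellState(), params)
        assert u == pytest.approx(sum(TABLE_MU_SENS) + MU_RES, rel=1e-12)
        assert u == pytest.approx(1.57510e-4, rel=1e-6)

    @pytest.mark.parametrize("gene", [Gene.EGFR, Gene.KRAS])
    def test_sensitized_cell_gains_only_matched_and_platinum_resistance(
        self, params, gene
    ):
        state = CellState(gene=gene)
        trans = enumerate_transitions(state, params)
        assert len(trans) == 2
        drugs = set()
        for t in trans:
            assert t.target.gene is gene  # never a second sensitization
            for d, _ in t.target.resistance:
                drugs.add(d)
        assert drugs == {INHIBITOR_FOR[gene], DrugClass.PT}
        assert total_transition_rate(state, params) == pytest.approx(2e-8, rel=1e-12)

    def test_resistance_accumulation_is_unbounded(self, params):
        state = CellState(gene=Gene.EGFR, resistance={DrugClass.EGFRI: 1})
        trans = enumerate_transitions(state, params)
        assert len(trans) == 2
        assert total_transition_rate(state, params) == pytest.approx(2e-8, rel=1e-12)
        counts = {t.target.resistance_count(DrugClass.EGFRI) for t in trans}
        assert 2 in counts  # the count keeps climbing

    def test_transitions_change_exactly_one_field(self, params):
        for src in [CellState(), CellState(gene=Gene.MET, resistance={DrugClass.PT: 3})]:
            for t in enumerate_transitions(src, params):
                gene_changed = t.target.gene is not src.gene
                res_changed = t.target.total_resistance == src.total_resistance + 1
                assert gene_changed != res_changed
                assert t.prob > 0

    def test_total_rate_is_additive_in_gene_rates(self, params):
        mu = dict(params.mu_sens)
        removed = mu.pop(Gene.KRAS)
        slim = ModelParams(s=params.s, mu_sens=mu, mu_res=dict(params.mu_res))
        full_u = total_transition_rate(CellState(), params)
        slim_u = total_transition_rate(CellState(), slim)
        assert full_u - slim_u == pytest.approx(removed, rel=1e-9)

    def test_zero_rates_give_zero_total(self):
        p = ModelParams(
            s=0.05, mu_sens={g: 0.0 for g in SENSITIZING_GENES},
            mu_res={d: 0.0 for d in DrugClass},
        )
        assert total_transition_rate(CellState(), p) == 0.0
        assert enumerate_transitions(CellState(), p) == []


class TestModelParams:
    def test_defaults_roundtrip_through_json(self, tmp_path):
        p = ModelParams.default()
        path = tmp_path / "params.json"
        p.to_json(path)
        q = ModelParams.from_json(path)
        assert q == p
        assert q.mu_sens[Gene.KRAS] == pytest.approx(3.15e-5)
        assert q.mu_res[DrugClass.PT] == pytest.approx(1e-8)
        assert q.signature_threshold == 0.05
        assert q.cells_per_cm3 == 1e9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"s": -0.01},
            {"s": 1.0},
            {"signature_threshold": 1.5},
            {"cells_per_cm3": 0},
            {"mu_sens": {Gene.KRAS: 2.0}},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
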