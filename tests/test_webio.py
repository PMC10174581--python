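import json

import numpy as np
import pytest

from kweb import (
    FoodWeb,
    FoodWebValidationError,
    augment_with_environment,
    fixture_web,
    read_flow_matrix_tsv,
    read_foodweb_json,
    read_s1_json,
    summarize,
    weighted_connectance,
    write_flow_matrix_tsv,
    write_foodweb_json,
)

from printed_tables import CONNECTANCE_ROWS


class TestValidation:
    def test_duplicate_species_rejected(self):
        with pytest.raises(FoodWebValidationError, match="duplicate"):
            FoodWeb("w", ("A", "A"), np.zeros((2, 2)), [1, 1], [0, 0], [0, 0])

    @pytest.mark.parametrize("field", ["imports", "exports", "respiration"])
    def test_negative_vector_rejected(self, field):
        kwargs = dict(imports=[1, 1], exports=[0, 0], respiration=[0, 0])
        kwargs[field] = [1, -1]
        with pytest.raises(FoodWebValidationError, match=field):
            FoodWeb("w", ("A", "B"), np.zeros((2, 2)), **kwargs)

    def test_non_square_flows_rejected(self):
        with pytest.raises(FoodWebValidationError, match="flows"):
            FoodWeb("w", ("A", "B"), np.zeros((2, 3)), [1, 1], [0, 0], [0, 0])

    def test_cannibalism_allowed_and_counted(self):
        web = FoodWeb("w", ("A",), [[2.0]], [5], [1], [1])
        assert summarize(web).C_n == 1


class TestJsonRoundTrip:
    def test_round_trip_identity(self, tmp_path, chain3):
        path = tmp_path / "chain3.json"
        write_foodweb_json(chain3, path)
        assert read_foodweb_json(path).equals(chain3)

    def test_chain_fixture_shape(self, tmp_path, chain3):
        path = tmp_path / "w.json"
        write_foodweb_json(chain3, path)
        web = read_foodweb_json(path)
        assert web.n_species == 3
        assert np.count_nonzero(web.flows) == 2

    def test_missing_key_named(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"species": ["A"], "imports": [1]}))
        with pytest.raises(FoodWebValidationError, match="flows"):
            read_foodweb_json(path)

    def test_ragged_matrix_rejected(self, tmp_path):
        payload = {
            "species": ["A", "B"],
            "flows": [[0, 1], [0]],
            "imports": [1, 0],
            "exports": [0, 0],
            "respiration": [0, 0],
        }
        path = tmp_path / "ragged.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(FoodWebValidationError, match="ragged"):
            read_foodweb_json(path)


class TestTsv:
    @pytest.mark.parametrize("name", ["chain3", "two_prey", "rank_swap", "isolated"])
    def test_tsv_json_cross_format_equality(self, tmp_path, name):
        web = fixture_web(name)
        jpath, tpath = tmp_path / "w.json", tmp_path / "w.tsv"
        write_foodweb_json(web, jpath)
        write_flow_matrix_tsv(web, tpath)
        assert read_flow_matrix_tsv(tpath).equals(read_foodweb_json(jpath))

    def test_empty_flow_matrix(self, tmp_path):
        web = FoodWeb("w", ("A", "B", "C"), np.zeros((3, 3)),
                      [10, 10, 10], [1, 1, 1], [1, 1, 1])
        path = tmp_path / "w.tsv"
        write_flow_matrix_tsv(web, path)
        assert summarize(read_flow_matrix_tsv(path)).C_n == 0

    def test_non_numeric_cell_position_reported(self, tmp_path, chain3):
        path = tmp_path / "w.tsv"
        write_flow_matrix_tsv(chain3, path)
        text = path.read_text().replace("5.0", "NA", 1)
        path.write_text(text)
        with pytest.raises(FoodWebValidationError, match=r"row \d+, column \d+"):
            read_flow_matrix_tsv(path)


class TestS1Adapter:
    def test_mapping_translates_keys(self, tmp_path, chain3):
        payload = {
            "web_name": "chain3",
            "nodes": list(chain3.species),
            "flux": chain3.flows.tolist(),
            "inp": chain3.imports.tolist(),
            "outp": chain3.exports.tolist(),
            "resp": chain3.respiration.tolist(),
        }
        src = tmp_path / "s1.json"
        src.write_text(json.dumps(payload))
        mapping = {
            "name": "web_name", "species": "nodes", "flows": "flux",
            "imports": "inp", "exports": "outp", "respiration": "resp",
        }
        assert read_s1_json(src, mapping).equals(chain3)

    def test_unknown_structure_fails_loudly(self, tmp_path):
        src = tmp_path / "s1.json"
        src.write_text(json.dumps({"something": 1}))
        with pytest.raises(FoodWebValidationError, match="available keys"):
            read_s1_json(src, {"species": "nodes", "flows": "flux",
                               "imports": "inp", "exports": "outp",
                               "respiration": "resp"})


class TestAugmentation:
    def test_chain_baseline_inflow(self, chain3_aug):
        assert np.allclose(chain3_aug.baseline_inflow, [10, 5, 2])

    def test_env_vectors(self, chain3_aug, chain3):
        assert np.array_equal(chain3_aug.env_out, chain3.imports)
        assert np.allclose(chain3_aug.env_in, chain3.exports + chain3.respiration)

    def test_zero_imports_baseline_is_column_sums(self):
        web = FoodWeb("w", ("A", "B"), [[0, 3], [1, 0]], [0, 0], [0, 0], [0, 0])
        aug = augment_with_environment(web)
        assert np.allclose(aug.baseline_inflow, web.flows.sum(axis=0))
        assert not aug.env_out.any()

    def test_idempotent(self, chain3):
        once = augment_with_environment(chain3)
        twice = augment_with_environment(once.base)
        assert np.array_equal(once.baseline_inflow, twice.baseline_inflow)
        assert once.base.equals(twice.base)

    def test_never_changes_interspecies_flows(self, chain3):
        before = chain3.flows.copy()
        augment_with_environment(chain3)
        assert np.array_equal(chain3.flows, before)

    def test_zero_inflow_species_warn_not_error(self, caplog):
        web = FoodWeb("w", ("A", "B"), [[0, 0], [0, 0]], [1, 0], [0, 0], [0, 0])
        with caplog.at_level("WARNING", logger="kweb"):
            aug = augment_with_environment(web)
        assert aug.baseline_inflow[1] == 0
        assert any("zero baseline inflow" in r.message for r in caplog.records)


class TestSummaries:
    @pytest.mark.parametrize("s,c_n,printed_c", CONNECTANCE_ROWS)
    def test_connectance_matches_printed_values(self, s, c_n, printed_c):
        rng = np.random.default_rng(s + c_n)
        flows = np.zeros(s * s)
        flows[rng.choice(s * s, size=c_n, replace=False)] = rng.lognormal(size=c_n)
        web = FoodWeb("w", tuple(f"s{i}" for i in range(s)),
                      flows.reshape(s, s), np.ones(s), np.ones(s), np.ones(s))
        summ = summarize(web)
        assert summ.S == s and summ.C_n == c_n
        assert round(summ.C, 3) == printed_c

    def test_empty_web_connectance_zero(self):
        web = FoodWeb("w", ("A", "B", "C"), np.zeros((3, 3)),
                      [1, 1, 1], [0, 0, 0], [0, 0, 0])
        summ = summarize(web)
        assert summ.C == 0 and summ.C_w == 0

    def test_uniform_weights_reduce_to_binary_connectance(self):
        # L equal-weight links: effective links = L, so C_w = C
        rng = np.random.default_rng(7)
        s, links = 12, 30
        flows = np.zeros(s * s)
        flows[rng.choice(s * s, size=links, replace=False)] = 2.5
        web = FoodWeb("w", tuple(f"s{i}" for i in range(s)),
                      flows.reshape(s, s), np.ones(s), np.ones(s), np.ones(s))
        summ = summarize(web)
        assert summ.C_w == pytest.approx(summ.C)

    def test_single_link_effective_connectance(self):
        web = FoodWeb("w", ("A", "B", "C"),
                      [[0, 4.2, 0], [0, 0, 0], [0, 0, 0]],
                      [1, 0, 0], [0, 0, 0], [0, 0, 0])
        assert weighted_connectance(web) == pytest.approx(1 / 9)

    def test_skewed_weights_give_cw_below_c(self):
        web = FoodWeb("w", ("A", "B", "C"),
                      [[0, 100, 0.01], [0, 0, 0.01], [0, 0, 0]],
                      [1, 0, 0], [0, 0, 0], [0, 0, 0])
        summ = summarize(web)
        assert 0 < summ.C_w < summ.C
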