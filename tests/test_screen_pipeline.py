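import pytest

from csabminer import datasets
from csabminer.io_formats import GenomeAssembly, PeptideSet
from csabminer.motif_profile import compile_profile, scan_profile
from csabminer.orf_mining import CILIATE_CODE, find_orfs
from csabminer.screen_pipeline import (
    AdapterResult,
    ConfigError,
    PredictorAdapter,
    ScreenConfig,
    collapse_topology,
    consensus_amp,
    heuristic_signal_adapter,
    make_permissive_adapters,
    make_truth_stub_adapters,
    reported,
    run_screen,
    topology_filter,
)
from csabminer.synthetic_data import (
    SyntheticConfig,
    SyntheticTruth,
    make_synthetic_assembly,
    score_recovery,
)


class TestConsensus:
    def test_unanimous_is_amp(self):
        assert consensus_amp([True, True, True]) is True

    def test_single_dissent_rejects(self):
        assert consensus_amp([True, True, False]) is False

    def test_single_adapter_suffices(self):
        assert consensus_amp([True]) is True

    def test_zero_adapters_is_config_error(self):
        with pytest.raises(ConfigError):
            consensus_amp([])


class TestTopologyFilter:
    @pytest.mark.parametrize(
        "ss, expected",
        [
            ("CCCHHHHHHCCEEEECCEEEECC", True),    # αββ
            ("EEECHHHHHCCEEEECCEEEC", True),      # βαββ
            ("HHHH", False),
            ("EEEEHHHHEEEE", False),              # αβ only -> HEE? no: EHE
            ("CCCC", False),
        ],
    )
    def test_examples(self, ss, expected):
        assert topology_filter(ss) is expected

    def test_short_runs_dropped(self):
        # 2-residue strand ignored at min_run=3, counted at min_run=2
        ss = "HHHHCCEEECCEECCEEE"
        assert collapse_topology(ss, 3) == "HEE"
        assert collapse_topology(ss, 2) == "HEEE"

    def test_alphabet_violation(self):
        with pytest.raises(ValueError):
            topology_filter("HHQX")


def _assembly_with_plant(seed=1, **kwargs):
    cfg = SyntheticConfig(
        seed=seed,
        n_scaffolds=2,
        scaffold_length_range=(20_000, 20_000),
        n_planted=kwargs.pop("n_planted", 1),
        **kwargs,
    )
    return make_synthetic_assembly(cfg), cfg


class TestRunScreen:
    def test_empty_assembly(self):
        truth = SyntheticTruth()
        cands = run_screen(GenomeAssembly({}), ScreenConfig(), make_truth_stub_adapters(truth))
        assert cands == []

    def test_single_plant_round_trip(self):
        (assembly, truth), _ = _assembly_with_plant(seed=5)
        cands = run_screen(assembly, ScreenConfig(), make_truth_stub_adapters(truth))
        hits = reported(cands)
        assert len(hits) == 1
        assert hits[0].mature_seq == truth.planted[0].mature_seq
        assert hits[0].signal_end == truth.planted[0].signal_end
        assert hits[0].annotation is not None

    def test_unanimity_one_dissenting_amp_predictor_rejects_all(self):
        (assembly, truth), _ = _assembly_with_plant(seed=5)
        adapters = make_truth_stub_adapters(truth)
        dissent = PredictorAdapter(
            "always-non-amp", "amp_score", lambda p: AdapterResult(False, "non-AMP")
        )
        hits = reported(run_screen(assembly, ScreenConfig(), adapters + [dissent]))
        assert hits == []

    def test_adapter_exception_marks_stage_error_not_pass(self):
        (assembly, truth), _ = _assembly_with_plant(seed=5)
        adapters = [a for a in make_truth_stub_adapters(truth) if a.kind != "transmembrane"]

        def boom(p):
            raise RuntimeError("predictor offline")

        adapters.append(PredictorAdapter("broken-tm", "transmembrane", boom))
        cands = run_screen(assembly, ScreenConfig(), adapters)
        assert reported(cands) == []
        errs = [v for c in cands for v in c.verdicts if v.detail.startswith("stage_error")]
        assert errs and all(not v.passed for v in errs)

    def test_monotonicity_adding_a_stage_never_grows_the_report(self):
        (assembly, truth), _ = _assembly_with_plant(seed=9, n_planted=2)

        def coords(cands):
            return {(c.orf.scaffold_id, c.orf.start, c.orf.end) for c in cands}

        base = coords(reported(run_screen(assembly, ScreenConfig(), make_permissive_adapters())))
        strict = coords(reported(run_screen(assembly, ScreenConfig(), make_truth_stub_adapters(truth))))
        assert strict <= base

    def test_permissive_stubs_reduce_to_orf_plus_detection(self):
        (assembly, truth), cfg = _assembly_with_plant(seed=3)
        config = ScreenConfig()
        hits = reported(run_screen(assembly, config, make_permissive_adapters()))
        profile = compile_profile(config.pattern_text)
        orfs = find_orfs(assembly, CILIATE_CODE, config.min_aa, config.max_aa)
        expected = {
            (o.scaffold_id, o.start, o.end)
            for o in orfs
            if scan_profile(o.aa_seq, profile, mode="any")
        }
        assert {(c.orf.scaffold_id, c.orf.start, c.orf.end) for c in hits} == expected
        assert expected  # the plant is in there

    def test_homology_or_profile_union(self):
        """With combine_mode=or, a reference-set hit alone passes detection."""
        (assembly, truth), _ = _assembly_with_plant(seed=5)
        refs = PeptideSet({"ref": truth.planted[0].precursor_seq})
        config = ScreenConfig(pattern_text="WWWWWWWW", reference_set=refs)  # profile can't hit
        hits = reported(run_screen(assembly, config, make_truth_stub_adapters(truth)))
        assert len(hits) == 1
        assert hits[0].best_hit == "ref"

    def test_missing_amp_adapter_rejected(self):
        (assembly, truth), _ = _assembly_with_plant(seed=5)
        adapters = [a for a in make_truth_stub_adapters(truth) if a.kind != "amp_score"]
        with pytest.raises(ConfigError):
            run_screen(assembly, ScreenConfig(), adapters)


class TestHeuristicSignalAdapter:
    def test_accepts_bundled_precursors_rejects_hydrophilic(self):
        adapter = heuristic_signal_adapter()
        res = adapter(datasets.LSAMP1_PRECURSOR)
        assert res.passed and res.signal_end == 20
        assert not adapter("MDEDEDEDEDEDEDEDEDEDEDEDE").passed
        assert not adapter("ACDEF").passed
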