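import numpy as np
import pytest

from surfppi import io_formats as io
from surfppi import pipeline
from surfppi.asa_predictor import RsaTrack, predict_stage1, train_cascade
from surfppi.synthetic import (
    SynthConfig,
    adhesive_template,
    gen_interactions,
    gen_proteins,
    surface_triad_types,
    template_triads,
    write_dataset,
)


class TestDeterminism:
    def test_proteins_identical_across_runs(self):
        cfg = SynthConfig(seed=3, n_proteins=6)
        a = gen_proteins(cfg)
        b = gen_proteins(cfg)
        for pa, pb in zip(a, b):
            assert pa.record.residues == pb.record.residues
            np.testing.assert_array_equal(pa.profile.raw, pb.profile.raw)
            np.testing.assert_array_equal(pa.rsa.values, pb.rsa.values)

    def test_pairs_identical_across_runs(self):
        cfg = SynthConfig(seed=3, n_proteins=20)
        prots = gen_proteins(cfg)
        assert gen_interactions(prots, cfg) == gen_interactions(prots, cfg)

    def test_different_seeds_differ(self):
        a = gen_proteins(SynthConfig(seed=1, n_proteins=4))
        b = gen_proteins(SynthConfig(seed=2, n_proteins=4))
        assert any(
            pa.record.residues != pb.record.residues for pa, pb in zip(a, b)
        )


class TestDatasetFiles:
    def test_written_files_parse_back(self, tmp_path):
        cfg = SynthConfig(seed=5, n_proteins=12)
        prots = gen_proteins(cfg)
        pairs = gen_interactions(prots, cfg)
        write_dataset(prots, pairs, tmp_path)

        records = io.read_fasta(tmp_path / "proteins.fasta")
        assert [r.id for r in records] == [p.record.id for p in prots]
        for rec in records[:3]:
            prof = io.read_pssm(tmp_path / "pssm" / f"{rec.id}.pssm", rec.id)
            assert prof.letters == rec.residues
            table = io.read_rsa_table(tmp_path / "rsa" / f"{rec.id}.rsa", rec.id)
            assert len(table) == len(rec)
        back = io.read_pairs(tmp_path / "pairs.tsv")
        assert back == pairs


class TestInteractionRule:
    def test_labels_follow_shared_sticky_rule_without_noise(self):
        cfg = SynthConfig(seed=7, n_proteins=20, label_noise=0.0)
        prots = gen_proteins(cfg)
        pairs = gen_interactions(prots, cfg)
        sticky = template_triads(cfg)
        types = {p.record.id: surface_triad_types(p, cfg) for p in prots}
        for pr in pairs:
            shared = len(sticky & types[pr.id_a] & types[pr.id_b])
            expected = shared > cfg.theta
            assert (pr.label is io.PairLabel.INTERACTING) == expected

    def test_pairs_are_balanced(self):
        cfg = SynthConfig(seed=7, n_proteins=20)
        pairs = gen_interactions(gen_proteins(cfg), cfg)
        n_pos = sum(p.label is io.PairLabel.INTERACTING for p in pairs)
        assert n_pos == len(pairs) - n_pos

    def test_empty_surface_shares_nothing(self):
        cfg = SynthConfig(seed=7)
        sticky = template_triads(cfg)
        assert len(sticky & set() & {1, 2, 3}) == 0  # rule forces negative

    def test_degenerate_rule_rate_rejected(self):
        cfg = SynthConfig(seed=7, n_proteins=20, p_adhesive=0.0, p_decoy=0.0)
        prots = gen_proteins(cfg)
        with pytest.raises(ValueError, match="positives"):
            gen_interactions(prots, cfg)

    def test_template_is_deterministic_and_charged(self):
        cfg = SynthConfig(seed=9)
        tpl = adhesive_template(cfg)
        assert tpl == adhesive_template(cfg)
        assert set(tpl) <= set("RKDEC")

    def test_sticky_override_respected(self):
        cfg = SynthConfig(seed=9, sticky_triads=(1, 2, 3))
        assert template_triads(cfg) == frozenset({1, 2, 3})


class TestPlantedSignals:
    def test_zero_exposure_signal_defeats_stage1(self):
        # negative control: without the exposure signal the profile carries
        # no information about RSA, so stage 1 cannot beat the mean predictor
        cfg = SynthConfig(seed=13, n_proteins=24, exposure_signal=0.0)
        prots = gen_proteins(cfg)
        tr, te = prots[:18], prots[18:]
        training = [
            (pipeline.profile_to_pssm2sp(p.profile),
             RsaTrack(p.record.id, p.rsa.values))
            for p in tr
        ]
        model = train_cascade(training)
        const = np.mean(np.concatenate([p.rsa.values for p in tr]))
        mae_model, mae_const = [], []
        for p in te:
            p2sp = pipeline.profile_to_pssm2sp(p.profile)
            mae_model.append(
                np.abs(predict_stage1(model, p2sp).values - p.rsa.values).mean()
            )
            mae_const.append(np.abs(const - p.rsa.values).mean())
        assert np.mean(mae_model) > np.mean(mae_const) - 0.01

    def test_adhesive_proteins_show_sticky_surface_types(self):
        cfg = SynthConfig(seed=17, n_proteins=30)
        prots = gen_proteins(cfg)
        sticky = template_triads(cfg)
        adh = [len(sticky & surface_triad_types(p, cfg))
               for p in prots if p.is_adhesive]
        rest = [len(sticky & surface_triad_types(p, cfg))
                for p in prots if not p.is_adhesive]
        assert np.mean(adh) > np.mean(rest) + 2

    def test_linear_mode_rsa_is_deterministic_function_of_profile(self):
        cfg = SynthConfig(seed=19, n_proteins=4, rsa_mode="profile_linear")
        a = gen_proteins(cfg)
        b = gen_proteins(cfg)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.rsa.values, pb.rsa.values)
            assert 0.0 <= pa.rsa.values.min() <= pa.rsa.values.max() <= 1.0


def _surface_pipeline_fm(cfg, shuffle_labels=False):
    """Test F-measure of the full pipeline (predicted surfaces) under the
    split protocol, optionally with labels destroyed by shuffling."""
    import warnings

    from surfppi.evaluation import ProtocolConfig, run_split_protocol
    from surfppi.surface import SurfaceParams

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prots = gen_proteins(cfg)
        pairs = gen_interactions(prots, cfg)
        y = np.array(
            [1 if p.label is io.PairLabel.INTERACTING else 0 for p in pairs]
        )
        if shuffle_labels:
            y = np.random.default_rng(cfg.seed + 999).permutation(y)
        records = [p.record for p in prots]
        training = [
            (pipeline.profile_to_pssm2sp(p.profile),
             RsaTrack(p.record.id, p.rsa.values))
            for p in prots
        ]
        model = train_cascade(training)
        tracks = pipeline.predict_tracks(model, [p.profile for p in prots])

        def featurize(params):
            surfs = pipeline.call_surfaces(tracks, SurfaceParams(t=0.5, w=9, o=3))
            return pipeline.pair_features(
                pairs, pipeline.triad_vectors(records, surfs)
            )

        npos = int(y.sum())
        pc = ProtocolConfig(
            n_train=min(120, npos - 60), n_val=30, n_test=30, repeats=3,
            seed=cfg.seed,
        )
        grid = [
            {"beta": b, "ks": k, "kt": kt}
            for b in (0.1, 0.2, 0.35, 0.5) for k in (1, 3) for kt in (10, "all")
        ]
        return run_split_protocol(y, featurize, grid, pc)["aggregate"][
            "f_measure"
        ]["mean"]


class TestPlantedSignalRecovery:
    def test_strong_signal_recovered_end_to_end(self):
        # exact motif copies + strong exposure signal: the full pipeline
        # (predicted surfaces included) must recover the planted labels
        fms = [
            _surface_pipeline_fm(
                SynthConfig(
                    seed=s, n_proteins=50, exposure_signal=6.0,
                    motif_copies=3, motif_mutation_rate=0.0,
                )
            )
            for s in (1, 2, 3, 4, 5)
        ]
        assert np.mean(fms) > 0.8

    def test_shuffled_labels_give_chance_performance(self):
        fms = [
            _surface_pipeline_fm(SynthConfig(seed=s), shuffle_labels=True)
            for s in (1, 2, 3, 4, 5)
        ]
        assert abs(np.mean(fms) - 0.5) < 0.1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 1},
            {"length_range": (5, 4)},
            {"rsa_mode": "nope"},
            {"label_noise": 1.5},
            {"motif_length": 2},
            {"background_groups": (0, 9)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(seed=1, **kwargs)
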