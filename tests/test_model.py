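"""Priors, read placement and the LAP-style likelihood.

The placement sum is cross-checked against an independent brute-force
enumeration written with plain Python loops.
"""

import math

import numpy as np
import pytest

from bayesasm import simulate
from bayesasm.model import (
    GammaPrior,
    PriorConfig,
    ReadModel,
    lap_score,
    log_likelihood,
    log_prior,
    placement_log_prob,
    read_log_prob,
)
from bayesasm.read_io import revcomp

# -- independent oracle -------------------------------------------------


def brute_force_read_log_prob(read, contigs, model, circular=None):
    """Direct enumeration of every placement on every strand of every
    contig, in plain Python."""
    circ = [False] * len(contigs) if circular is None else list(circular)
    ell = len(read)
    denom = 0
    total = 0.0
    for contig, is_circ in zip(contigs, circ):
        L = len(contig)
        if ell > L:
            continue
        hay = contig + contig[: ell - 1] if is_circ else contig
        n = L if is_circ else L - ell + 1
        denom += n
        for q in (read, revcomp(read)):
            for start in range(n):
                p = 1.0
                for a, b in zip(q, hay[start : start + ell]):
                    if a == b:
                        p *= 1 - model.error_rate
                    else:
                        p *= model.error_rate / 3
                total += p
    denom *= 2
    if denom == 0 or total == 0.0:
        return model.floor(ell, denom)
    return math.log(total) - math.log(denom)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestGammaPrior:
    @pytest.mark.parametrize("shape", [2.0, 5.0, 10.0, 50.0])
    def test_mode_parameterization_exact(self, shape):
        p = GammaPrior(shape=shape, center=5386.0)
        assert (shape - 1) * p.scale == pytest.approx(5386.0)

    def test_shape_must_exceed_one(self):
        with pytest.raises(ValueError):
            GammaPrior(shape=1.0, center=10.0)

    @pytest.mark.parametrize("shape", [2.0, 5.0, 10.0, 50.0])
    def test_length_argmax_at_center(self, shape):
        cfg = PriorConfig(
            length_prior=GammaPrior(shape=shape, center=5386.0),
            contig_prior=GammaPrior(shape=5.0, center=1.0),
        )
        xs = np.arange(1, 20001)
        vals = [log_prior(x, 1, cfg) for x in xs]
        assert xs[int(np.argmax(vals))] == 5386

    def test_contig_argmax_at_one(self):
        cfg = PriorConfig()
        vals = [log_prior(5386, n, cfg) for n in range(1, 51)]
        assert int(np.argmax(vals)) == 0  # n_contigs = 1

    def test_flat_mode_zero(self):
        cfg = PriorConfig(mode="flat")
        assert log_prior(123.0, 7, cfg) == 0.0

    def test_degenerate_state_floored(self):
        cfg = PriorConfig()
        assert log_prior(0, 0, cfg) < -1e9


class TestPlacement:
    def test_exact_match_zero_error(self):
        m = ReadModel(error_rate=0.0)
        assert placement_log_prob("ACGT", "ACGT", 0, "+", m) == 0.0

    def test_one_mismatch_product(self):
        m = ReadModel(error_rate=0.01)
        got = placement_log_prob("AC", "AA", 0, "+", m)
        assert got == pytest.approx(math.log(0.99) + math.log(0.01 / 3))

    def test_mismatch_with_zero_error_is_minus_inf(self):
        m = ReadModel(error_rate=0.0)
        assert placement_log_prob("AC", "AA", 0, "+", m) == -math.inf

    def test_reverse_strand(self):
        m = ReadModel(error_rate=0.0)
        assert placement_log_prob("ACGT", revcomp("ACGT"), 0, "-", m) == 0.0

    def test_out_of_range_start(self):
        m = ReadModel()
        with pytest.raises(ValueError):
            placement_log_prob("ACGT", "ACG", 0, "+", m)


class TestReadLogProb:
    def test_identical_contig_scores_half(self):
        # one exact forward placement; denominator 2 (both strands)
        m = ReadModel(error_rate=0.0)
        assert read_log_prob("ACGTAC", ["ACGTAC"], m) == pytest.approx(
            math.log(0.5)
        )

    def test_absent_read_floored(self):
        m = ReadModel(error_rate=0.0)
        got = read_log_prob("AAAA", ["CCCCCCCC"], m)
        assert got == m.floor(4, 2 * 5)

    def test_doubled_contig_matches_brute_force(self):
        rng = np.random.default_rng(4)
        contig = _random_seq(rng, 30)
        read = contig[10:18]
        m = ReadModel(error_rate=0.0)
        doubled = contig + contig
        assert read_log_prob(read, [doubled], m) == pytest.approx(
            brute_force_read_log_prob(read, [doubled], m), abs=1e-12
        )

    @pytest.mark.parametrize("error_rate", [0.01, 0.1])
    def test_matches_brute_force_on_random_instances(self, error_rate):
        rng = np.random.default_rng(17)
        m = ReadModel(error_rate=error_rate)
        for _ in range(100):
            contig = _random_seq(rng, int(rng.integers(10, 51)))
            read = _random_seq(rng, int(rng.integers(2, 11)))
            got = read_log_prob(read, [contig], m)
            want = brute_force_read_log_prob(read, [contig], m)
            assert got == pytest.approx(want, abs=1e-9)

    def test_circular_contig_matches_brute_force(self):
        rng = np.random.default_rng(23)
        m = ReadModel(error_rate=0.02)
        for _ in range(50):
            contig = _random_seq(rng, int(rng.integers(12, 40)))
            read = _random_seq(rng, int(rng.integers(2, 10)))
            got = read_log_prob(read, [contig], m, circular=[True])
            want = brute_force_read_log_prob(read, [contig], m, circular=[True])
            assert got == pytest.approx(want, abs=1e-9)

    def test_seeded_mode_agrees_with_exhaustive_on_clean_reads(self):
        rng = np.random.default_rng(31)
        contig = _random_seq(rng, 400)
        m_seed = ReadModel(error_rate=0.002, placement="seeded")
        m_ex = ReadModel(error_rate=0.002, placement="exhaustive")
        for start in range(0, 350, 37):
            read = contig[start : start + 50]
            assert read_log_prob(read, [contig], m_seed) == pytest.approx(
                read_log_prob(read, [contig], m_ex), rel=1e-9
            )


class TestLogLikelihood:
    def test_single_read_equals_read_log_prob(self):
        m = ReadModel(error_rate=0.01)
        contigs = ["ACGTACGT"]
        assert log_likelihood(contigs, ["ACGT"], m) == pytest.approx(
            read_log_prob("ACGT", contigs, m)
        )

    def test_total_is_n_times_lap(self):
        m = ReadModel(error_rate=0.01)
        contigs = ["ACGTACGTAA"]
        reads = ["ACGT", "GTAC", "TACG"]
        assert log_likelihood(contigs, reads, m) == pytest.approx(
            3 * lap_score(contigs, reads, m)
        )

    def test_empty_reads_zero(self):
        assert log_likelihood(["ACGT"], [], ReadModel()) == 0.0

    def test_true_genome_outscores_mutant(self):
        """With error-free reads, the generating sequence scores at least
        as high as a single-substitution mutant (strictly higher when the
        mutated site is covered)."""
        rng = np.random.default_rng(5)
        m = ReadModel(error_rate=0.01)
        wins = 0
        trials = 20
        for _ in range(trials):
            genome = _random_seq(rng, 120)
            doubled = genome + genome
            reads = [
                doubled[i : i + 30]
                for i in rng.integers(0, 120, size=40)
            ]
            pos = int(rng.integers(120))
            alt = [b for b in "ACGT" if b != genome[pos]][0]
            mutant = genome[:pos] + alt + genome[pos + 1 :]
            if log_likelihood(
                [genome], reads, m, circular=[True]
            ) > log_likelihood([mutant], reads, m, circular=[True]):
                wins += 1
        assert wins >= trials - 1


class TestLogPosterior:
    def test_prior_only_ignores_reads(self, double_bubble, double_bubble_states):
        from bayesasm.model import log_posterior
        from bayesasm.state import state_stats

        cfg = PriorConfig(mode="prior_only")
        m = ReadModel()
        s = double_bubble_states[5]
        total, n = state_stats(s, double_bubble)
        want = log_prior(total, n, cfg)
        got = log_posterior(s, double_bubble, ["ACGTACGTACGTACG"], cfg, m)
        assert got == pytest.approx(want)

    def test_cached_posterior_matches_direct(
        self, small_truth, double_bubble, double_bubble_states
    ):
        from bayesasm import read_io
        from bayesasm.model import CachedPosterior, log_posterior

        reads = read_io.oriented_sequences(small_truth.reads)[:50]
        cfg = PriorConfig(
            length_prior=GammaPrior(shape=5.0, center=600.0),
            contig_prior=GammaPrior(shape=5.0, center=1.0),
        )
        m = ReadModel(error_rate=0.002, placement="exhaustive")
        post = CachedPosterior(double_bubble, reads, cfg, m)
        for s in double_bubble_states[:8]:
            assert post(s) == pytest.approx(
                log_posterior(s, double_bubble, reads, cfg, m), rel=1e-9
            )
            # cache hit returns the same value
            assert post(s) == post(s)


class TestLoadConfig:
    def test_parses_keys_and_defaults(self, tmp_path):
        from bayesasm.model import load_config

        cfg = tmp_path / "model.cfg"
        cfg.write_text(
            "# priors\n"
            "prior.length.center=5386\n"
            "prior.length.shape=10\n"
            "prior.mode=flat\n"
            "model.error_rate=0.01\n"
        )
        priors, model = load_config(cfg)
        assert priors.length_prior.shape == 10
        assert priors.length_prior.center == 5386
        assert priors.contig_prior.center == 1.0  # default
        assert priors.mode == "flat"
        assert model.error_rate == 0.01

    def test_unknown_key_rejected(self, tmp_path):
        from bayesasm.model import load_config

        cfg = tmp_path / "model.cfg"
        cfg.write_text("prior.banana=1\n")
        with pytest.raises(ValueError):
            load_config(cfg)
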