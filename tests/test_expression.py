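import itertools

import numpy as np
import pytest

from dilipred.datatypes import GeneSignature
from dilipred.expression import (
    SampleFilter,
    collapse_to_drug,
    expression_block,
    select_correlated_samples,
    select_samples,
)

from conftest import make_sample


def random_samples(rng, n, genes=4):
    out = []
    for i in range(n):
        out.append(
            make_sample(
                f"s{i}", f"d{rng.integers(3)}",
                rng.choice(["PHH", "HEPG2", "MCF7"]),
                float(rng.choice([1.0, 10.0])),
                float(rng.choice([6.0, 24.0, 48.0])),
                rng.normal(size=genes),
            )
        )
    return out


class TestSelectSamples:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        flt = SampleFilter("PHH", 10.0, 24.0)
        for _ in range(20):
            samples = random_samples(rng, 15)
            expect = [
                s for s in samples
                if s.cell_line == "PHH" and s.dose == 10.0 and s.time >= 24.0
            ]
            got = select_samples(samples, flt)
            assert [s.sample_id for s in got] == [s.sample_id for s in expect]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        flt = SampleFilter("PHH", 10.0, 24.0)
        samples = random_samples(rng, 30)
        once = select_samples(samples, flt)
        assert select_samples(once, flt) == once

    def test_unset_filter_is_identity(self):
        rng = np.random.default_rng(2)
        samples = random_samples(rng, 10)
        assert select_samples(samples, SampleFilter(None, None, None)) == samples

    def test_empty_input(self):
        assert select_samples([], SampleFilter()) == []


class TestCollapseToDrug:
    def test_single_sample_passthrough(self):
        s = make_sample("s0", "d0", "PHH", 10, 24, [1.0, -2.0, 0.5])
        vec = collapse_to_drug([s])
        np.testing.assert_allclose(vec.loc["d0"].to_numpy(), [1.0, -2.0, 0.5])

    def test_median_of_replicates(self):
        samples = [
            make_sample("s0", "d0", "PHH", 10, 24, [1.0]),
            make_sample("s1", "d0", "PHH", 10, 24, [3.0]),
        ]
        assert collapse_to_drug(samples).loc["d0"].iloc[0] == 2.0

    def test_longest_time_wins_then_median(self):
        # 6 h sample discarded; collapse = per-gene median of the two 24 h
        samples = [
            make_sample("s0", "d0", "PHH", 10, 6, [100.0, 100.0, 100.0]),
            make_sample("s1", "d0", "PHH", 10, 24, [1.0, 4.0, -1.0]),
            make_sample("s2", "d0", "PHH", 10, 24, [3.0, 2.0, -3.0]),
        ]
        np.testing.assert_allclose(
            collapse_to_drug(samples).loc["d0"].to_numpy(), [2.0, 3.0, -2.0]
        )

    def test_drugs_without_samples_are_absent(self):
        s = make_sample("s0", "d0", "PHH", 10, 24, [0.0])
        assert list(collapse_to_drug([s]).index) == ["d0"]


def correlated_oracle(samples, threshold=0.5):
    """Exhaustive all-pairs reference implementation."""
    pairs = []
    for a, b in itertools.combinations(samples, 2):
        if a.cell_line == b.cell_line:
            continue
        xa, xb = a.zscores.to_numpy(), b.zscores.to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            continue
        pairs.append((float(np.corrcoef(xa, xb)[0, 1]), a, b))
    if not pairs:
        retained = samples
    else:
        above = [p for p in pairs if p[0] > threshold] or [max(pairs, key=lambda p: p[0])]
        seen = {}
        for _, a, b in above:
            seen[a.sample_id] = a
            seen[b.sample_id] = b
        retained = list(seen.values())
    return np.median(np.stack([s.zscores.to_numpy() for s in retained]), axis=0)


class TestCorrelatedSamples:
    def test_lone_sample_returned_as_is(self):
        s = make_sample("s0", "d0", "PHH", 10, 24, [1.0, 2.0])
        np.testing.assert_allclose(select_correlated_samples([s]).to_numpy(), [1.0, 2.0])

    def test_matches_exhaustive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            samples = random_samples(rng, n, genes=12)
            got = select_correlated_samples(samples).to_numpy()
            np.testing.assert_allclose(got, correlated_oracle(samples), atol=1e-12)

    def test_high_correlation_pair_retained(self):
        base = np.arange(10.0)
        samples = [
            make_sample("a", "d", "PHH", 10, 24, base + 0.01 * np.arange(10)),
            make_sample("b", "d", "HEPG2", 10, 24, base + 0.02 * np.arange(10)),
            make_sample("c", "d", "MCF7", 10, 24, np.random.default_rng(0).normal(size=10)),
        ]
        got = select_correlated_samples(samples, threshold=0.5)
        expect = np.median(
            np.stack([samples[0].zscores.to_numpy(), samples[1].zscores.to_numpy()]), axis=0
        )
        np.testing.assert_allclose(got.to_numpy(), expect)

    def test_best_pair_kept_when_all_below_threshold(self):
        rng = np.random.default_rng(4)
        # three nearly-uncorrelated samples: only the single most correlated
        # cross-cell-line pair survives
        samples = [
            make_sample("a", "d", "PHH", 10, 24, rng.normal(size=30)),
            make_sample("b", "d", "HEPG2", 10, 24, rng.normal(size=30)),
            make_sample("c", "d", "MCF7", 10, 24, rng.normal(size=30)),
        ]
        rs = {
            (x.sample_id, y.sample_id): np.corrcoef(
                x.zscores.to_numpy(), y.zscores.to_numpy()
            )[0, 1]
            for x, y in itertools.combinations(samples, 2)
        }
        assert max(rs.values()) < 0.5  # fixture sanity
        best = max(rs, key=rs.get)
        keep = [s for s in samples if s.sample_id in best]
        expect = np.median(np.stack([s.zscores.to_numpy() for s in keep]), axis=0)
        np.testing.assert_allclose(
            select_correlated_samples(samples).to_numpy(), expect
        )

    def test_same_cell_line_pairs_ignored(self):
        base = np.arange(8.0)
        # the only high-r pair shares a cell line, so it must not qualify;
        # fallback picks the best cross-cell-line pair instead
        rng = np.random.default_rng(5)
        samples = [
            make_sample("a", "d", "PHH", 10, 24, base),
            make_sample("b", "d", "PHH", 10, 24, base + 0.001),
            make_sample("c", "d", "HEPG2", 10, 24, rng.normal(size=8)),
        ]
        got = select_correlated_samples(samples)
        cross = [
            np.corrcoef(s.zscores.to_numpy(), samples[2].zscores.to_numpy())[0, 1]
            for s in samples[:2]
        ]
        keep = samples[int(np.argmax(cross))]
        expect = np.median(
            np.stack([keep.zscores.to_numpy(), samples[2].zscores.to_numpy()]), axis=0
        )
        np.testing.assert_allclose(got.to_numpy(), expect)

    def test_requires_at_least_one_sample(self):
        with pytest.raises(ValueError):
            select_correlated_samples([])


class TestExpressionBlock:
    def test_column_per_signature_gene(self, tiny_cohort):
        from dilipred.expression import SampleFilter, collapse_to_drug, select_samples

        vec = collapse_to_drug(select_samples(tiny_cohort.samples, SampleFilter()))
        sig = GeneSignature(list(vec.columns[:7]))
        block = expression_block(vec, sig)
        assert block.values.shape[1] == 7
        assert set(block.blocks.values()) == {"expression"}

    def test_single_gene_block(self, tiny_cohort):
        from dilipred.expression import SampleFilter, collapse_to_drug, select_samples

        vec = collapse_to_drug(select_samples(tiny_cohort.samples, SampleFilter()))
        block = expression_block(vec, GeneSignature([vec.columns[0]]))
        assert block.values.shape[1] == 1

    def test_absent_gene_is_named_in_error(self, tiny_cohort):
        from dilipred.expression import SampleFilter, collapse_to_drug, select_samples

        vec = collapse_to_drug(select_samples(tiny_cohort.samples, SampleFilter()))
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            expression_block(vec, GeneSignature(["NOT_A_GENE"]))
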