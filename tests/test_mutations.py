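"""Variant filters vs a brute-force oracle; burden adjustment properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellclock import mutations as mut


def _ev(cell="c1", chrom="chr1", pos=100, ref="A", alt="T", tlod=20.0,
        depth=50, support=(("u1", 4, 4),)):
    return mut.VariantEvidence(
        cell_id=cell, donor_id="d1", chrom=chrom, pos=pos, ref=ref, alt=alt,
        tlod=tlod, exome_depth=depth, umi_support=tuple(support),
    )


class TestPrefilter:
    @pytest.mark.parametrize(
        "tlod,depth,ref,alt,kept",
        [
            (5.0, 50, "A", "T", False),   # TLOD at/below 5.3 removed
            (5.3, 50, "A", "T", False),
            (5.4, 50, "A", "T", True),
            (20.0, 8, "A", "T", False),   # exome depth must exceed 10
            (20.0, 10, "A", "T", False),
            (20.0, 11, "A", "T", True),
            (20.0, 50, "AT", "A", False),  # deletion removed
            (20.0, 50, "A", "AT", False),  # insertion removed
        ],
    )
    def test_gates(self, tlod, depth, ref, alt, kept):
        out = mut.prefilter_variants([_ev(tlod=tlod, depth=depth, ref=ref,
                                          alt=alt)])
        assert (len(out) == 1) is kept

    def test_indels_kept_when_snps_only_off(self):
        out = mut.prefilter_variants([_ev(ref="AT", alt="A")],
                                     snps_only=False)
        assert len(out) == 1


class TestUmiConsensus:
    @pytest.mark.parametrize(
        "alt_reads,total,passes",
        [(3, 4, True), (2, 2, False), (3, 7, False), (3, 6, False),
         (4, 6, True), (3, 5, True)],
    )
    def test_worked_examples(self, alt_reads, total, passes):
        record = _ev(support=((f"u", alt_reads, total),))
        assert mut.umi_consensus_filter(record) is passes

    def test_any_single_umi_suffices(self):
        record = _ev(support=(("u1", 1, 5), ("u2", 4, 4)))
        assert mut.umi_consensus_filter(record)

    def test_zero_read_umi_ignored_with_warning(self):
        record = _ev(support=(("u1", 0, 0), ("u2", 3, 4)))
        with pytest.warns(UserWarning, match="zero reads"):
            assert mut.umi_consensus_filter(record)

    @settings(max_examples=200, derandomize=True)
    @given(
        alt=st.integers(0, 20),
        extra=st.integers(0, 20),
        min_reads=st.integers(1, 5),
    )
    def test_rule_matches_definition(self, alt, extra, min_reads):
        total = alt + extra
        if total == 0:
            return
        record = _ev(support=(("u", alt, total),))
        expected = alt >= min_reads and alt / total > 0.5
        assert mut.umi_consensus_filter(record, min_reads=min_reads) is expected


class TestAlleleCap:
    def test_cap_rules(self):
        base = dict(cell="c", chrom="chr1", pos=10)
        three = [_ev(alt=a, **base) for a in "TGC"]
        assert mut.position_allele_cap(three) == []
        two = [_ev(alt=a, **base) for a in "TG"]
        assert mut.position_allele_cap(two) == two
        one = [_ev(alt="T", **base)]
        assert mut.position_allele_cap(one) == one

    def test_cap_is_per_cell(self):
        recs = [_ev(cell=c, alt=a, pos=10) for c in ("c1", "c2")
                for a in "TGC"]
        recs += [_ev(cell="c3", alt="T", pos=10)]
        out = mut.position_allele_cap(recs)
        assert [r.cell_id for r in out] == ["c3"]

    def test_idempotence_of_each_filter(self):
        rng = np.random.default_rng(0)
        recs = _random_table(rng, 40)
        pre = mut.prefilter_variants(recs)
        assert mut.prefilter_variants(pre) == pre
        cons = mut.consensus_supported(pre)
        assert mut.consensus_supported(cons) == cons
        capped = mut.position_allele_cap(cons)
        assert mut.position_allele_cap(capped) == capped


def _random_table(rng, n_records):
    """Random evidence tables exercising every rule boundary."""
    recs = []
    for i in range(n_records):
        n_umi = int(rng.integers(1, 4))
        support = []
        for j in range(n_umi):
            total = int(rng.integers(0, 9))
            alt = int(rng.integers(0, total + 1))
            support.append((f"u{i}_{j}", alt, total))
        ref, alt_allele = "A", str(rng.choice(list("TGC")))
        if rng.random() < 0.1:
            ref = "AT"  # indel
        recs.append(
            mut.VariantEvidence(
                cell_id=f"c{rng.integers(0, 4)}", donor_id="d",
                chrom="chr1", pos=int(rng.integers(1, 6)),
                ref=ref, alt=alt_allele,
                tlod=float(rng.uniform(0, 12)),
                exome_depth=int(rng.integers(0, 25)),
                umi_support=tuple(support),
            )
        )
    return recs


def _brute_force_oracle(records, tlod_min=5.3, depth_min=10, min_reads=3,
                        min_fraction=0.5, max_alleles=2):
    """Independent joint application of all filtering rules."""
    stage1 = []
    for r in records:
        if not (r.tlod > tlod_min and r.exome_depth > depth_min):
            continue
        if len(r.ref) != 1 or len(r.alt) != 1:
            continue
        ok = False
        for _, a, t in r.umi_support:
            if t > 0 and a >= min_reads and a / t > min_fraction:
                ok = True
        if ok:
            stage1.append(r)
    result = []
    for r in stage1:
        alts_here = {
            x.alt
            for x in stage1
            if (x.cell_id, x.chrom, x.pos) == (r.cell_id, r.chrom, r.pos)
        }
        if len(alts_here) <= max_alleles:
            result.append(r)
    return result


class TestFilterPipelineOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        recs = _random_table(rng, int(rng.integers(1, 51)))
        assert mut.filter_pipeline(recs) == _brute_force_oracle(recs)

    def test_counting_conservation(self):
        rng = np.random.default_rng(99)
        recs = _random_table(rng, 50)
        surv = mut.filter_pipeline(recs)
        counts = mut.count_mutations(surv, [f"c{i}" for i in range(4)])
        per_cell = {}
        for r in surv:
            per_cell.setdefault(r.cell_id, set()).add((r.chrom, r.pos, r.alt))
        for cell, n in counts.items():
            assert n == len(per_cell.get(cell, set()))


class TestCountAndAdjust:
    @staticmethod
    def _covariates(n, seed=0, constant=False):
        rng = np.random.default_rng(seed)
        if constant:
            vals = np.ones(n)
            return pd.DataFrame(
                {
                    "cell_umi_total": vals * 1000,
                    "cell_coverage": vals * 5e4,
                    "donor_exome_coverage": vals * 60,
                },
                index=[f"c{i}" for i in range(n)],
            )
        return pd.DataFrame(
            {
                "cell_umi_total": rng.integers(500, 2500, n).astype(float),
                "cell_coverage": rng.lognormal(10, 0.3, n),
                "donor_exome_coverage": rng.lognormal(4, 0.2, n),
            },
            index=[f"c{i}" for i in range(n)],
        )

    @staticmethod
    def _records_for_counts(counts):
        recs = []
        for cell, k in counts.items():
            for j in range(k):
                recs.append(_ev(cell=cell, pos=1000 + j))
        return recs

    def test_rescaled_range_is_exact(self):
        rng = np.random.default_rng(1)
        cov = self._covariates(50, seed=1)
        counts = {c: int(rng.integers(0, 12)) for c in cov.index}
        burden, _ = mut.count_and_adjust(
            self._records_for_counts(counts), cov
        )
        assert burden["adjusted_count"].min() == 0.0
        assert burden["adjusted_count"].max() == burden["raw_count"].max()

    def test_constant_covariates_monotone_in_raw(self):
        rng = np.random.default_rng(2)
        cov = self._covariates(40, constant=True)
        counts = {c: int(rng.integers(0, 10)) for c in cov.index}
        with pytest.warns(UserWarning):
            burden, info = mut.count_and_adjust(
                self._records_for_counts(counts), cov
            )
        srt = burden.sort_values("raw_count")
        assert (np.diff(srt["adjusted_count"]) >= -1e-9).all()

    def test_missing_covariates_dropped_and_floor(self):
        cov = self._covariates(12, seed=3)
        cov.iloc[0, 0] = np.nan
        burden, _ = mut.count_and_adjust([], cov)
        assert len(burden) == 11
        with pytest.raises(ValueError, match="at least 10"):
            mut.count_and_adjust([], self._covariates(5))


class TestBurdenVsPredictedAge:
    @staticmethod
    def _frames(seed=0, slope=0.1, n=400):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
        pred = rng.uniform(0, 90, n)
        burden = pd.DataFrame(
            {"adjusted_count": slope * pred + rng.normal(0, 1, n)}, index=idx
        )
        preds = pd.DataFrame({"predicted_age": pred}, index=idx)
        meta = pd.DataFrame(
            {
                "subset": np.where(np.arange(n) % 2 == 0, "Na", "EM"),
                "sex": "F",
                "group_id": "XS",
            },
            index=idx,
        )
        return burden, preds, meta

    def test_linearity_and_negative_control(self):
        burden, preds, meta = self._frames()
        out = mut.burden_vs_predicted_age(burden, preds, meta)
        out = out.set_index("subset")
        assert (out["slope"] > 0).all()
        assert (out["p_value"] < 1e-6).all()
        # doubling burdens doubles the slope
        out2 = mut.burden_vs_predicted_age(
            burden * 2.0, preds, meta
        ).set_index("subset")
        assert out2["slope"]["Na"] == pytest.approx(
            2 * out["slope"]["Na"], rel=1e-9
        )
        # shuffled predictions flatten it
        rng = np.random.default_rng(5)
        shuffled = preds.copy()
        shuffled["predicted_age"] = rng.permutation(
            shuffled["predicted_age"].to_numpy()
        )
        out3 = mut.burden_vs_predicted_age(
            burden, shuffled, meta
        ).set_index("subset")
        assert (out3["p_value"] > 0.001).all()

    def test_small_subset_reports_na(self):
        burden, preds, meta = self._frames(n=10)
        meta["subset"] = ["Na"] * 8 + ["tiny"] * 2
        out = mut.burden_vs_predicted_age(burden, preds, meta)
        row = out.set_index("subset").loc["tiny"]
        assert np.isnan(row["slope"]) and np.isnan(row["p_value"])


def test_variant_evidence_invariants():
    with pytest.raises(ValueError, match="read support"):
        _ev(support=(("u1", 5, 4),))
    with pytest.raises(ValueError, match="duplicate"):
        _ev(support=(("u1", 2, 4), ("u1", 3, 4)))
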