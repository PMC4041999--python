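"""Unit and property tests for the pileup filter cascade."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strainvar.calling import (
    StrainCalls,
    VariantClass,
    Zygosity,
    build_eve_blacklist,
    call_strain,
    classify_site,
    estimate_sensitivity,
    remove_duplicates,
)
from strainvar.config import CallingParams
from strainvar.pileup import pileup_from_observations

from conftest import make_site


def brute_force_classify(site, params: CallingParams):
    """Straight-line restatement of the calling rules, used as oracle."""
    n = site.depth_nodup
    if n == 0:
        return Zygosity.NO_DATA
    best_base, best_count = None, 0
    for base in "ACGT":
        if base == site.ref:
            continue
        c = site.counts.get(base, 0)
        if c > best_count:
            best_base, best_count = base, c
    ilen = max(len(site.indel_seq) - 1, 0)
    use_indel = (
        site.indel_count > 0
        and 1 <= ilen <= params.indel_max_len
        and site.indel_count > best_count
    )
    if best_base is None and not use_indel:
        return Zygosity.REFERENCE
    k = site.hq_count_alt
    f = k / n
    min_sup = params.min_support_indel if use_indel else params.min_support_snv
    if k >= params.min_calls and f >= min_sup:
        return Zygosity.HOMOZYGOUS_VARIANT
    if params.het_band[0] <= f < min_sup:
        return Zygosity.HETEROZYGOUS_EXCLUDED
    return Zygosity.REFERENCE


class TestRemoveDuplicates:
    def test_no_duplicates_is_identity(self):
        site = make_site(depth_nodup=10, depth=10, counts={"C": 10})
        assert remove_duplicates(site) == site

    def test_two_duplicates_removed(self):
        site = make_site(depth_nodup=10, depth=12, counts={"C": 10})
        assert remove_duplicates(site).depth == 10

    def test_all_reads_duplicates_of_one_start(self):
        site = make_site(depth_nodup=1, depth=8, counts={"C": 1})
        assert remove_duplicates(site).depth == 1


class TestClassifySite:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # thresholds met exactly: 3 of 4 reads (f = 0.75)
            (dict(depth_nodup=4, counts={"C": 3}), Zygosity.HOMOZYGOUS_VARIANT),
            # 60% support: heterozygous band for a SNV
            (dict(depth_nodup=10, counts={"C": 6}), Zygosity.HETEROZYGOUS_EXCLUDED),
            # same support for an indel clears the 40% indel threshold
            (
                dict(depth_nodup=10, indel_count=6, indel_seq="+AC"),
                Zygosity.HOMOZYGOUS_VARIANT,
            ),
            # below 75% support: not called (capillary-confirmed false
            # negatives behaved this way)
            (dict(depth_nodup=20, counts={"C": 14}), Zygosity.HETEROZYGOUS_EXCLUDED),
            # support below the band: reference
            (dict(depth_nodup=20, counts={"C": 2}), Zygosity.REFERENCE),
            # band lower edge is inclusive
            (dict(depth_nodup=20, counts={"C": 5}), Zygosity.HETEROZYGOUS_EXCLUDED),
            # enough support fraction but fewer than 3 quality calls
            (dict(depth_nodup=2, counts={"C": 2}), Zygosity.REFERENCE),
            # zero depth: no data
            (dict(depth_nodup=0, depth=0), Zygosity.NO_DATA),
            # indel in [0.25, 0.40): heterozygous-excluded
            (
                dict(depth_nodup=10, indel_count=3, indel_seq="-ACG"),
                Zygosity.HETEROZYGOUS_EXCLUDED,
            ),
            # 10 bp indel exceeds the short-indel limit: never called
            (
                dict(depth_nodup=10, indel_count=10, indel_seq="+ACGTACGTAC"),
                Zygosity.REFERENCE,
            ),
        ],
    )
    def test_cascade_rules(self, kwargs, expected):
        assert classify_site(make_site(**kwargs)).zygosity is expected

    def test_boundary_call_beats_het_band(self):
        """Exactly 75% support with >= 3 quality calls is a call."""
        site = make_site(depth_nodup=8, counts={"G": 6}, ref="A")
        result = classify_site(site)
        assert result.zygosity is Zygosity.HOMOZYGOUS_VARIANT
        assert result.call.support_fraction == pytest.approx(0.75)

    def test_indel_call_shape(self):
        site = make_site(ref="G", depth_nodup=10, indel_count=9, indel_seq="-TT")
        call = classify_site(site).call
        assert call.variant_class is VariantClass.DELETION
        assert call.ref == "GTT" and call.alt == "G"

    def test_high_quality_flag_tracks_depth(self):
        assert classify_site(make_site(depth_nodup=8, counts={"C": 8})).call.high_quality
        assert not classify_site(make_site(depth_nodup=7, counts={"C": 7})).call.high_quality

    @given(
        n=st.integers(0, 40),
        k_frac=st.floats(0.0, 1.0),
        hq_frac=st.floats(0.0, 1.0),
        is_indel=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_zygosity_classes_partition_sites(self, n, k_frac, hq_frac, is_indel):
        """Every site lands in exactly one of the four classes and the
        scalar path agrees with the written rules."""
        support = int(round(n * k_frac))
        hq = int(round(support * hq_frac))
        if is_indel:
            site = make_site(
                depth_nodup=n, indel_count=support, indel_seq="+AG", hq=hq
            )
        else:
            site = make_site(depth_nodup=n, counts={"T": support}, hq=hq, ref="A")
        params = CallingParams()
        result = classify_site(site, params)
        assert result.zygosity in set(Zygosity)
        assert (result.call is not None) == (
            result.zygosity is Zygosity.HOMOZYGOUS_VARIANT
        )
        assert result.zygosity is brute_force_classify(site, params)

    @given(
        n=st.integers(1, 40),
        support=st.integers(0, 40),
        sup_lo=st.floats(0.4, 1.0),
        sup_hi=st.floats(0.4, 1.0),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_raising_support_threshold_never_adds_calls(
        self, n, support, sup_lo, sup_hi
    ):
        support = min(support, n)
        lo, hi = sorted((sup_lo, sup_hi))
        site = make_site(depth_nodup=n, counts={"C": support}, ref="A")
        loose = classify_site(site, CallingParams(min_support_snv=lo))
        strict = classify_site(site, CallingParams(min_support_snv=hi))
        if strict.zygosity is Zygosity.HOMOZYGOUS_VARIANT:
            assert loose.zygosity is Zygosity.HOMOZYGOUS_VARIANT

    @given(n=st.integers(1, 40), support=st.integers(0, 40), mc=st.integers(1, 6))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_lowering_min_calls_never_removes_calls(self, n, support, mc):
        support = min(support, n)
        site = make_site(depth_nodup=n, counts={"C": support}, ref="A")
        strict = classify_site(site, CallingParams(min_calls=mc))
        loose = classify_site(site, CallingParams(min_calls=max(1, mc - 1)))
        if strict.zygosity is Zygosity.HOMOZYGOUS_VARIANT:
            assert loose.zygosity is Zygosity.HOMOZYGOUS_VARIANT


def _random_boundary_sites(rng: np.random.Generator, n_sites: int):
    """Sites spanning the filter boundaries (exact 75%/40%/25% fractions,
    minimum call counts, indel length limits, multi-allelic mixes)."""
    sites = []
    for i in range(n_sites):
        ref = "ACGT"[rng.integers(0, 4)]
        style = rng.integers(0, 3)
        if style == 0:  # random multinomial site
            n = int(rng.integers(0, 30))
            w = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 2.0))
            counts = rng.multinomial(n, w)
            cdict = {b: int(c) for b, c in zip("ACGT", counts)}
            indel = int(rng.integers(0, 4)) if rng.random() < 0.2 else 0
            seq = "+" + "A" * int(rng.integers(1, 12)) if indel else ""
        elif style == 1:  # exact-fraction boundary site
            n = int(rng.choice([4, 8, 10, 12, 16, 20]))
            f = float(rng.choice([0.2, 0.25, 0.4, 0.5, 0.6, 0.75, 0.8, 1.0]))
            k = int(round(n * f))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            cdict = {ref: n - k, alt: k}
            indel, seq = 0, ""
        else:  # indel-dominant site
            n = int(rng.integers(1, 25))
            indel = int(rng.integers(1, n + 1))
            seq = ("+" if rng.random() < 0.5 else "-") + "C" * int(
                rng.integers(1, 11)
            )
            cdict = {ref: n - indel}
        nonref = {b: c for b, c in cdict.items() if b != ref and c > 0}
        dom = max(nonref.values()) if nonref else 0
        dom = max(dom, indel)
        hq = int(rng.integers(0, dom + 1)) if rng.random() < 0.5 else dom
        sites.append(
            make_site(
                ref=ref,
                depth_nodup=sum(cdict.values()) + indel,
                counts=cdict,
                indel_count=indel,
                indel_seq=seq,
                hq=hq,
                pos=i,
            )
        )
    return sites


class TestCallStrain:
    def test_empty_pileup(self):
        pu = pileup_from_observations("S", [], {"chr1": 100})
        out = call_strain(pu)
        assert out.calls == {} and out.stats.n_het_excluded == 0

    def test_matches_per_site_oracle_on_boundary_sites(self):
        rng = np.random.default_rng(99)
        sites = _random_boundary_sites(rng, 2000)
        pu = pileup_from_observations("S", sites, {"chr1": 2000})
        out = call_strain(pu)
        params = CallingParams()
        for site in sites:
            want = brute_force_classify(site, params)
            key = (site.chrom, site.pos)
            assert (key in out.calls) == (want is Zygosity.HOMOZYGOUS_VARIANT)
            assert (key in out.het_positions) == (
                want is Zygosity.HETEROZYGOUS_EXCLUDED
            )

    def test_blacklisted_position_removed_and_tallied(self):
        sites = [
            make_site(depth_nodup=10, counts={"C": 10}, pos=5),
            make_site(depth_nodup=10, counts={"C": 10}, pos=7),
        ]
        pu = pileup_from_observations("S", sites, {"chr1": 100})
        out = call_strain(pu, blacklist={("chr1", 5)})
        assert ("chr1", 5) not in out.calls and ("chr1", 7) in out.calls
        assert out.stats.n_blacklist_removed == 1

    def test_unsorted_pileup_rejected(self):
        sites = [
            make_site(depth_nodup=10, counts={"C": 10}, pos=7),
            make_site(depth_nodup=10, counts={"C": 10}, pos=5),
        ]
        pu = pileup_from_observations("S", sites, {"chr1": 100})
        pu.chroms["chr1"].sites = pu.chroms["chr1"].sites.iloc[::-1].reset_index(
            drop=True
        )
        with pytest.raises(ValueError, match="sorted"):
            call_strain(pu)

    def test_callable_fractions(self):
        sites = [make_site(depth_nodup=d, counts={}, pos=i) for i, d in enumerate([2, 3, 9, 20])]
        pu = pileup_from_observations("S", sites, {"chr1": 4})
        out = call_strain(pu)
        assert out.stats.callable_fraction_min_calls == pytest.approx(3 / 4)
        assert out.stats.callable_fraction_hq == pytest.approx(2 / 4)


class TestEveBlacklist:
    def test_eve_identical_to_reference_gives_empty_blacklist(self):
        sites = [make_site(depth_nodup=20, counts={"A": 20}, ref="A", pos=i) for i in range(5)]
        pu = pileup_from_observations("Eve", sites, {"chr1": 10})
        assert build_eve_blacklist(pu) == set()

    def test_planted_reference_error_is_blacklisted(self):
        sites = [
            make_site(depth_nodup=20, counts={"A": 20}, ref="A", pos=0),
            make_site(depth_nodup=20, counts={"T": 20}, ref="A", pos=3),
        ]
        pu = pileup_from_observations("Eve", sites, {"chr1": 10})
        assert build_eve_blacklist(pu) == {("chr1", 3)}

    def test_sixty_percent_support_not_blacklisted(self):
        sites = [make_site(depth_nodup=10, counts={"T": 6}, ref="A", pos=0)]
        pu = pileup_from_observations("Eve", sites, {"chr1": 10})
        assert build_eve_blacklist(pu) == set()


class TestSensitivity:
    def _calls_with(self, positions_alts):
        import pandas as pd

        sc = StrainCalls(strain="S1")
        for pos, alt in positions_alts:
            site = make_site(depth_nodup=10, counts={alt: 10}, ref="A", pos=pos)
            sc.calls[("chr1", pos)] = classify_site(site).call
        return sc

    def test_exact_ratio(self):
        import pandas as pd

        calls = self._calls_with([(i, "C") for i in range(97)])
        panel = pd.DataFrame(
            {
                "chrom": ["chr1"] * 100,
                "pos": list(range(100)),
                "ref": ["A"] * 100,
                "S1": ["C"] * 100,
            }
        )
        assert estimate_sensitivity(calls, panel, "S1") == pytest.approx(0.97)

    def test_full_recovery_is_one(self):
        import pandas as pd

        calls = self._calls_with([(0, "C"), (1, "G")])
        panel = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [0, 1],
                "ref": ["A", "A"],
                "S1": ["C", "G"],
            }
        )
        assert estimate_sensitivity(calls, panel, "S1") == 1.0

    def test_no_differing_markers_is_an_error(self):
        import pandas as pd

        calls = self._calls_with([])
        panel = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [0], "ref": ["A"], "S1": ["A"]}
        )
        with pytest.raises(ValueError):
            estimate_sensitivity(calls, panel, "S1")
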