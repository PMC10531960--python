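import pytest

from hemiopsin import tuning
from hemiopsin.tuning import (
    DEFAULT_CONSERVATIVE_GROUPS,
    classify_site,
    collect_site_states,
    compare_lineages,
    is_conservative,
    site_label,
    survey_clades,
)


class TestConservative:
    @pytest.mark.parametrize(
        "x,a,expected",
        [
            ("V", "I", True),   # branched aliphatics
            ("L", "V", True),
            ("R", "K", True),
            ("K", "V", False),  # charge loss counts as non-conservative
            ("F", "Y", False),  # aromatic swap still counted
            ("Q", "Q", True),
        ],
    )
    def test_default_groups(self, x, a, expected):
        assert is_conservative(x, a) is expected
        assert is_conservative(a, x) is expected  # symmetric


class TestSiteStates:
    def test_minor_variant_filtered_from_focal(self, aphid_fixture):
        """A single divergent UV-der member (T at site 102) does not
        enter the clade state set at the default 0.25 threshold."""
        fx = aphid_fixture
        sm = next(s for s in fx["sitemaps"] if s.scheme == "Rhodopsin")
        st = collect_site_states(
            fx["alignment"], sm, 102, fx["uv_der"], fx["uv_anc"], fx["outgroups"]
        )
        assert st.focal == {"K"}
        assert "T" in st.raw.values()

    def test_sister_set_unfiltered(self, aphid_fixture):
        fx = aphid_fixture
        sm = next(s for s in fx["sitemaps"] if s.scheme == "Rhodopsin")
        st = collect_site_states(
            fx["alignment"], sm, 85, fx["uv_der"], fx["uv_anc"], fx["outgroups"]
        )
        assert st.sister == {"V", "L", "C"}

    def test_uniform_focal_clade(self, aphid_fixture):
        fx = aphid_fixture
        sm = next(s for s in fx["sitemaps"] if s.scheme == "Rhodopsin")
        for frac in (0.0, 0.25, 0.6):
            st = collect_site_states(
                fx["alignment"], sm, 90, fx["uv_der"], fx["uv_anc"],
                fx["outgroups"], minor_variant_fraction=frac,
            )
            assert st.focal == {"V"}

    def test_focal_set_monotone_in_threshold(self, aphid_fixture):
        """Shrinking the minor-variant fraction never removes residues."""
        fx = aphid_fixture
        sm = next(s for s in fx["sitemaps"] if s.scheme == "Rhodopsin")
        for site in sm.site_to_column:
            prev = None
            for frac in (0.6, 0.25, 0.1, 0.0):
                st = collect_site_states(
                    fx["alignment"], sm, site, fx["uv_der"], fx["uv_anc"],
                    fx["outgroups"], minor_variant_fraction=frac,
                )
                if prev is not None:
                    assert prev <= st.focal
                prev = st.focal


class TestClassify:
    def get_states(self, fx, site, focal_key, sister_key, scheme="Rhodopsin"):
        sm = next(s for s in fx["sitemaps"] if s.scheme == scheme)
        return collect_site_states(
            fx["alignment"], sm, site, fx[focal_key], fx[sister_key], fx["outgroups"]
        )

    def test_site90_derived_replacement(self, aphid_fixture):
        c = classify_site(self.get_states(aphid_fixture, 90, "uv_der", "uv_anc"))
        assert c.verdict == "derived_in_focal"
        assert c.replacement == ("K", "V")
        assert c.catalog_hit

    def test_site294_shared_derived(self, aphid_fixture):
        c = classify_site(self.get_states(aphid_fixture, 294, "uv_der", "uv_anc"))
        assert c.verdict == "shared_derived"

    def test_site43_sister_not_ancestral(self, aphid_fixture):
        c = classify_site(self.get_states(aphid_fixture, 43, "uv_der", "uv_anc"))
        assert c.verdict == "ambiguous"
        assert c.note == "sister_not_ancestral"

    def test_conservative_change_not_derived(self, planthopper_fixture):
        # planthopper site 43: ancestral I/L, UV-der V — aliphatic swap
        c = classify_site(self.get_states(planthopper_fixture, 43, "uv_der", "uv_anc"))
        assert c.verdict == "ambiguous"
        assert c.note == "conservative_change"

    def test_verdicts_partition_sites(self, aphid_survey):
        valid = {"derived_in_focal", "retained", "shared_derived", "ambiguous"}
        for by_site in aphid_survey.classifications.values():
            assert len(by_site) == 27
            for c in by_site.values():
                assert c.verdict in valid
                if c.verdict == "derived_in_focal":
                    assert c.replacement is not None

    def test_no_site_derived_in_both_clades(self, aphid_survey, planthopper_survey):
        for rep in (aphid_survey, planthopper_survey):
            der, anc = rep.focal_labels
            assert not set(rep.derived_sites(der)) & set(rep.derived_sites(anc))


class TestSurveyAndCompare:
    def test_counts_match_site_lists(self, aphid_survey):
        for label in aphid_survey.classifications:
            assert aphid_survey.derived_count(label) == len(
                aphid_survey.derived_sites(label)
            )

    def test_ambiguous_sites_not_in_counts(self, planthopper_survey):
        for label in planthopper_survey.classifications:
            amb = {k for k, _ in planthopper_survey.ambiguous_sites(label)}
            assert not amb & set(planthopper_survey.derived_sites(label))

    def test_compare_symmetry(self, aphid_survey, planthopper_survey):
        ab = compare_lineages(aphid_survey, planthopper_survey)
        ba = compare_lineages(planthopper_survey, aphid_survey)
        assert ab.parallel_sites == ba.parallel_sites
        assert ab.n_non_shared == ba.n_non_shared

    def test_parallel_plus_nonshared_accounting(self, aphid_survey, planthopper_survey):
        cmp = compare_lineages(aphid_survey, planthopper_survey)
        n_x = aphid_survey.derived_count("UV-der")
        n_y = planthopper_survey.derived_count("UV-der")
        assert 2 * cmp.n_parallel + cmp.n_non_shared == n_x + n_y

    def test_overlapping_clades_rejected(self, aphid_fixture):
        fx = aphid_fixture
        bad = tuning.CladeDefinition("UV-anc", fx["uv_der"].members[:2])
        with pytest.raises(ValueError, match="disjoint"):
            survey_clades(
                fx["alignment"], fx["sitemaps"], bad, fx["uv_der"], fx["outgroups"]
            )

    def test_site_label_rendering(self):
        assert site_label(90, "Rhodopsin") == "90"
        assert site_label(29, "CrUVop2") == "29*"
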