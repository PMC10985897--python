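"""Sexual-lineage hypermethylation criteria and the SLM / canonical split."""

import numpy as np
import pandas as pd
import pytest

from dmrkit import (
    SlhParams,
    TruthProfile,
    build_genome,
    identify_slh,
    sex_average,
    simulate_track,
    slh_feature_summary,
    split_slh,
)
from dmrkit.errors import ConfigurationError
from dmrkit.simulate import plant_slh_loci, truth_slh_frame
from dmrkit.slm import SLH_COLUMNS

from conftest import make_annotation, make_track

SEX = ("meiocyte", "microspore", "sperm")


def one_bin_track(levels, bin_index=0, coverage=100, cell_type="", replicate=1):
    """Single 100-bp bin with 5 cytosines per context at exact levels.

    ``levels`` maps context -> methylation fraction; fractions must be
    multiples of 1/coverage so the per-cytosine level is exact.
    """
    base = bin_index * 100
    rows = []
    offsets = {"CG": 1, "CHG": 11, "CHH": 21}
    for context, level in levels.items():
        n_meth = round(level * coverage)
        assert abs(n_meth / coverage - level) < 1e-12
        for i in range(5):
            rows.append(
                ("chr1", base + offsets[context] + i, "+", context,
                 n_meth, coverage - n_meth)
            )
    return make_track(rows, cell_type=cell_type, replicate=replicate)


def _sex_somatic(sex_levels, somatic_levels):
    sex = {
        ct: [one_bin_track(sex_levels, cell_type=ct, replicate=r) for r in (1, 2)]
        for ct in SEX
    }
    som = [
        one_bin_track(somatic_levels, cell_type="seedling", replicate=r)
        for r in (1, 2)
    ]
    return sex, som


class TestSexAverage:
    def test_chg_average_excludes_sperm(self):
        tracks = {
            "meiocyte": one_bin_track({"CHG": 0.4}),
            "microspore": one_bin_track({"CHG": 0.6}),
            "sperm": one_bin_track({"CHG": 0.1}),
        }
        out = sex_average(tracks, "CHG")
        assert out.loc[0, "level"] == pytest.approx(0.5)

    def test_chh_average_is_three_way(self):
        tracks = {
            "meiocyte": one_bin_track({"CHH": 0.1}),
            "microspore": one_bin_track({"CHH": 0.2}),
            "sperm": one_bin_track({"CHH": 0.3}),
        }
        out = sex_average(tracks, "CHH")
        assert out.loc[0, "level"] == pytest.approx(0.2)

    def test_bin_missing_in_one_cell_type_skipped(self):
        tracks = {
            "meiocyte": one_bin_track({"CHH": 0.1}, bin_index=0),
            "microspore": one_bin_track({"CHH": 0.2}, bin_index=1),  # different bin
            "sperm": one_bin_track({"CHH": 0.3}, bin_index=0),
        }
        assert sex_average(tracks, "CHH").empty

    def test_missing_cell_type_rejected(self):
        with pytest.raises(ConfigurationError):
            sex_average({"meiocyte": one_bin_track({"CHG": 0.4})}, "CHG")


class TestIdentifySlh:
    def test_sum_rule_rejects_small_composite_difference(self):
        # per-context diffs (0.01, 0.06, 0.12) pass individually, sum 0.19 < 0.4
        sex, som = _sex_somatic(
            {"CG": 0.51, "CHG": 0.16, "CHH": 0.22},
            {"CG": 0.50, "CHG": 0.10, "CHH": 0.10},
        )
        assert identify_slh(sex, som).empty

    def test_all_criteria_met_yields_locus(self):
        # diffs (0.10, 0.15, 0.20), sum 0.45; counts large enough for p < 0.01
        sex, som = _sex_somatic(
            {"CG": 0.60, "CHG": 0.25, "CHH": 0.30},
            {"CG": 0.50, "CHG": 0.10, "CHH": 0.10},
        )
        loci = identify_slh(sex, som)
        assert len(loci) == 1
        assert loci.loc[0, "diff_sum"] == pytest.approx(0.45)
        assert loci.loc[0, "p_value"] < 0.01
        assert list(loci.columns) == SLH_COLUMNS

    def test_negative_cg_difference_rejected(self):
        # diffs (-0.01, 0.30, 0.30), sum 0.59, but Diff_CG > 0 fails
        sex, som = _sex_somatic(
            {"CG": 0.49, "CHG": 0.40, "CHH": 0.40},
            {"CG": 0.50, "CHG": 0.10, "CHH": 0.10},
        )
        assert identify_slh(sex, som).empty

    def test_replicate_ordering_required(self):
        # strong average difference, but one sex replicate sits below the soma
        sex, som = _sex_somatic(
            {"CG": 0.60, "CHG": 0.40, "CHH": 0.40},
            {"CG": 0.30, "CHG": 0.05, "CHH": 0.05},
        )
        sex["sperm"][1] = one_bin_track(
            {"CG": 0.01, "CHG": 0.01, "CHH": 0.01},
            cell_type="sperm", replicate=2,
        )
        assert identify_slh(sex, som).empty

    def test_missing_cell_type_is_configuration_error(self):
        sex, som = _sex_somatic(
            {"CG": 0.6, "CHG": 0.3, "CHH": 0.3}, {"CG": 0.5, "CHG": 0.1, "CHH": 0.1}
        )
        del sex["sperm"]
        with pytest.raises(ConfigurationError):
            identify_slh(sex, som)
        with pytest.raises(ConfigurationError):
            identify_slh({**sex, "sperm": sex["meiocyte"]}, [])

    def test_relaxing_thresholds_never_loses_loci(self, small_genome):
        truth = TruthProfile.uniform(list(SEX) + ["seedling"])
        truth = plant_slh_loci(small_genome, truth, 8, seed=5)
        sex = {
            ct: [simulate_track(small_genome, truth, ct, r, seed=5) for r in (1, 2)]
            for ct in SEX
        }
        som = [simulate_track(small_genome, truth, "seedling", r, seed=5) for r in (1, 2)]
        strict = identify_slh(sex, som)
        relaxed = identify_slh(
            sex, som,
            SlhParams(min_diff_cg=-1, min_diff_chg=0.0, min_diff_chh=0.0,
                      min_diff_sum=0.2),
        )
        assert len(relaxed) >= len(strict)
        strict_keys = set(map(tuple, strict[["chrom", "start"]].to_numpy()))
        relaxed_keys = set(map(tuple, relaxed[["chrom", "start"]].to_numpy()))
        assert strict_keys <= relaxed_keys


class TestSplitSlh:
    def _loci(self, somatic_chg, somatic_chh):
        row = {c: 0.0 for c in SLH_COLUMNS}
        row.update(
            chrom="chr1", start=0, end=100,
            somatic_chg=somatic_chg, somatic_chh=somatic_chh,
        )
        return pd.DataFrame([row])[SLH_COLUMNS]

    @pytest.mark.parametrize(
        "chh,chg,expected",
        [
            (0.03, 0.08, "SLM"),
            (0.06, 0.08, "canonical_SLH"),
            (0.03, 0.12, "canonical_SLH"),
            (0.05, 0.10, "canonical_SLH"),  # boundary: SLM needs strict <
        ],
    )
    def test_somatic_nonCG_levels_decide_class(self, chh, chg, expected):
        out = split_slh(self._loci(somatic_chg=chg, somatic_chh=chh))
        assert out.loc[0, "classification"] == expected

    def test_undefined_somatic_level_excluded_with_warning(self):
        loci = pd.concat(
            [self._loci(0.02, 0.01), self._loci(np.nan, 0.01)], ignore_index=True
        )
        with pytest.warns(UserWarning, match="somatic"):
            out = split_slh(loci)
        assert len(out) == 1

    def test_classes_partition_loci(self, small_genome):
        truth = TruthProfile.uniform(list(SEX) + ["seedling"])
        truth = plant_slh_loci(small_genome, truth, 10, seed=6)
        sex = {
            ct: [simulate_track(small_genome, truth, ct, r, seed=6) for r in (1, 2)]
            for ct in SEX
        }
        som = [simulate_track(small_genome, truth, "seedling", r, seed=6) for r in (1, 2)]
        classified = split_slh(identify_slh(sex, som))
        n_slm = (classified["classification"] == "SLM").sum()
        n_canon = (classified["classification"] == "canonical_SLH").sum()
        assert n_slm + n_canon == len(classified) > 0
        truth_frame = truth_slh_frame(truth)
        joined = classified.merge(truth_frame, on=["chrom", "start", "end"])
        assert (joined["classification"] == joined["intended"]).all()


class TestFeatureSummary:
    def test_counts_by_class(self):
        loci = pd.DataFrame(
            [
                {**{c: 0.0 for c in SLH_COLUMNS}, "chrom": "chr1", "start": 0,
                 "end": 100, "classification": "SLM"},
                {**{c: 0.0 for c in SLH_COLUMNS}, "chrom": "chr1", "start": 5000,
                 "end": 5100, "classification": "canonical_SLH"},
            ]
        )
        ann = make_annotation(
            [("chr1", 0, 2000, "gene", "g1"), ("chr1", 4900, 5600, "TE", "te1")]
        )
        table = slh_feature_summary(loci, ann)
        assert table.loc["SLM", "gene"] == 1
        assert table.loc["canonical_SLH", "TE"] == 1
        assert table.to_numpy().sum() == 2

    def test_empty_loci_all_zero(self):
        table = slh_feature_summary(
            pd.DataFrame(columns=SLH_COLUMNS + ["classification"]),
            make_annotation([("chr1", 0, 2000, "gene", "g1")]),
        )
        assert (table.to_numpy() == 0).all()

    def test_unannotated_locus_is_intergenic(self):
        loci = pd.DataFrame(
            [{**{c: 0.0 for c in SLH_COLUMNS}, "chrom": "chr1", "start": 0,
              "end": 100, "classification": "SLM"}]
        )
        ann = make_annotation([("chr1", 90_000, 95_000, "gene", "g1")])
        table = slh_feature_summary(loci, ann)
        assert table.loc["SLM", "intergenic"] == 1
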