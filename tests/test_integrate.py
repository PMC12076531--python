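"""Parameter-table parsing, enrichment factors and absolute-unit conversion."""

import numpy as np
import pandas as pd
import pytest

from absquant import synthetic as syn
from absquant.ingest import read_report
from absquant.integrate import (
    AVOGADRO,
    EnrichmentFactor,
    EnrichmentStandards,
    ExperimentalParams,
    compute_enrichment,
    expected_ms_share_fmol,
    read_params,
    read_standards,
    srm_enrichment,
    to_absolute,
)
from absquant.preprocess import remove_flagged
from absquant.quantify import AbsoluteQuantResult, quantify_samples, read_anchors

# the worked example of a complete parameters table: three conditions, one
# plain, one concentrated (1:10 standards), one enriched (1:2 standards)
PARAMS_TABLE = """\
Condition\tSampleVolume\tProteinConcentration\tAmountMS\tCellsPerML\tTotalCultureVolume\tProteinSRM\tfmolSRM\tEnrichment\tEnrichmentMode\tStdDilution\tStdVolume
Cond1_t0\t2.31\t2.99\t9.67\t4.54\t7.54\tTNAMLN\t4.44\tFALSE\t\t\t
Cond2_t1\t2.5\t0.2\t4.1\t5.13\t2.62\tAJFVYC\t4.85\tTRUE\tConcentration\t10\t10
Cond3_t2\t7.38\t6.56\t2.77\t3.66\t3.8\tBYEKSC\t9.71\tTRUE\tEnrichment\t2\t10
"""


@pytest.fixture
def params_path(tmp_path):
    path = tmp_path / "params.tsv"
    path.write_text(PARAMS_TABLE)
    return path


def _result(rows) -> AbsoluteQuantResult:
    df = pd.DataFrame(rows, columns=["protein_id", "sample", "intensity", "fmol_ms",
                                     "provenance"])
    return AbsoluteQuantResult(data=df)


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

def test_reference_parameter_rows_parse_exactly(params_path):
    records = read_params(params_path)
    assert [p.condition for p in records] == ["Cond1_t0", "Cond2_t1", "Cond3_t2"]
    p1, p2, p3 = records
    assert (p1.sample_volume_ul, p1.protein_conc_ug_per_ul, p1.amount_ms_ug) == (
        2.31, 2.99, 9.67)
    assert (p1.cells_per_ml, p1.total_culture_volume) == (4.54, 7.54)
    assert p1.protein_srm == ["TNAMLN"] and p1.fmol_srm == [4.44]
    assert p1.enrichment is False and p1.enrichment_mode is None
    assert p2.enrichment is True and p2.enrichment_mode == "Concentration"
    assert (p2.std_dilution, p2.std_volume_ul) == (10.0, 10.0)
    assert p3.enrichment_mode == "Enrichment"
    assert (p3.std_dilution, p3.std_volume_ul) == (2.0, 10.0)


def test_params_tsv_and_xlsx_equivalent(params_path, tmp_path):
    df = pd.read_csv(params_path, sep="\t")
    xlsx = tmp_path / "params.xlsx"
    df.to_excel(xlsx, index=False)
    assert read_params(xlsx) == read_params(params_path)


def test_comma_separated_srm_lists(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "Condition\tSampleVolume\tProteinConcentration\tAmountMS\tProteinSRM\tfmolSRM\tEnrichment\n"
        "C1\t2\t5\t5\tP1,P2\t4.0,6.0\tTRUE\n"
    )
    (p,) = read_params(path)
    assert p.protein_srm == ["P1", "P2"]
    assert p.fmol_srm == [4.0, 6.0]


def test_enrichment_true_without_mode_or_srm_rejected(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "Condition\tSampleVolume\tProteinConcentration\tAmountMS\tEnrichment\n"
        "C1\t2\t5\t5\tTRUE\n"
    )
    with pytest.raises(ValueError, match="Enrichment is TRUE"):
        read_params(path)


def test_optional_columns_may_be_absent(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "Condition\tSampleVolume\tProteinConcentration\tAmountMS\nC1\t2\t5\t5\n"
    )
    (p,) = read_params(path)
    assert p.protein_srm is None and p.cells_per_ml is None
    assert p.enrichment is False


def test_missing_mandatory_column_named(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("Condition\tSampleVolume\tAmountMS\nC1\t2\t5\n")
    with pytest.raises(ValueError, match="ProteinConcentration"):
        read_params(path)


# ---------------------------------------------------------------------------
# enrichment from spiked standards
# ---------------------------------------------------------------------------

def _enriched_params(**kw):
    defaults = dict(
        condition="Enr", sample_volume_ul=10.0, protein_conc_ug_per_ul=5.0,
        amount_ms_ug=5.0, enrichment=True, enrichment_mode="Enrichment",
        std_dilution=10.0, std_volume_ul=10.0,
    )
    defaults.update(kw)
    return ExperimentalParams(**defaults)


def test_enrichment_factor_arithmetic():
    """Stock 100/10 x 10 µL = 100 fmol added; 5/50 µg injected -> 10 fmol expected."""
    p = _enriched_params(sample_volume_ul=10.0, protein_conc_ug_per_ul=5.0)
    assert expected_ms_share_fmol(p, 100.0) == pytest.approx(10.0)
    result = _result([("STD1", "Enr_1", 1e5, 20.0, "observed")])
    factor = compute_enrichment(result, p, EnrichmentStandards({"STD1": 100.0}))
    assert factor.factor == pytest.approx(2.0)
    assert factor.basis == "spiked_standards"


def test_enrichment_factor_median_of_two():
    p = _enriched_params()
    result = _result([
        ("STD1", "Enr_1", 1e5, 20.0, "observed"),   # ratio 2.0
        ("STD2", "Enr_1", 1e5, 40.0, "observed"),   # ratio 4.0
    ])
    std = EnrichmentStandards({"STD1": 100.0, "STD2": 100.0})
    assert compute_enrichment(result, p, std).factor == pytest.approx(3.0)


def test_enrichment_missing_standard_skipped():
    p = _enriched_params()
    result = _result([("STD1", "Enr_1", 1e5, 20.0, "observed")])
    std = EnrichmentStandards({"STD1": 100.0, "GHOST": 50.0})
    with pytest.warns(UserWarning, match="GHOST"):
        factor = compute_enrichment(result, p, std)
    assert factor.n_standards == 1
    with pytest.raises(ValueError, match="no usable"):
        compute_enrichment(result, p, EnrichmentStandards({"GHOST": 50.0}))


def test_enrichment_recovery_from_synthetic_scenario(tmp_path):
    """Planted factor f=5 with 3 standards and sigma=0.1 recovered within 15%."""
    spec = syn.SyntheticSpec(n_proteins=150, noise_sigma=0.1,
                             enrichment_factor=5.0, seed=17)
    ds = syn.make_enrichment_scenario(spec, tmp_path)
    rep = remove_flagged(read_report(ds.report_path))
    result = quantify_samples(rep, read_anchors(ds.anchors_path), "iBAQ")
    params = read_params(ds.params_path)
    p_enr = next(p for p in params if p.enrichment)
    factor = compute_enrichment(result, p_enr, read_standards(ds.standards_path))
    assert factor.factor == pytest.approx(5.0, rel=0.15)


def test_enrichment_noiseless_is_exact(tmp_path):
    spec = syn.SyntheticSpec(n_proteins=50, noise_sigma=0.0,
                             enrichment_factor=5.0, seed=4)
    ds = syn.make_enrichment_scenario(spec, tmp_path)
    rep = remove_flagged(read_report(ds.report_path))
    result = quantify_samples(rep, read_anchors(ds.anchors_path), "iBAQ")
    p_enr = next(p for p in read_params(ds.params_path) if p.enrichment)
    factor = compute_enrichment(result, p_enr, read_standards(ds.standards_path))
    assert factor.factor == pytest.approx(5.0, rel=1e-6)


# ---------------------------------------------------------------------------
# enrichment from supplied (targeted-MS) amounts
# ---------------------------------------------------------------------------

def test_srm_enrichment_ratio_and_median():
    p = _enriched_params(protein_srm=["P1"], fmol_srm=[10.0],
                         enrichment_mode=None, std_dilution=None, std_volume_ul=None)
    result = _result([("P1", "Enr_1", 1e5, 30.0, "observed")])
    assert srm_enrichment(result, p).factor == pytest.approx(3.0)

    p2 = _enriched_params(protein_srm=["P1", "P2"], fmol_srm=[10.0, 10.0])
    result2 = _result([
        ("P1", "Enr_1", 1e5, 20.0, "observed"),  # ratio 2
        ("P2", "Enr_1", 1e5, 80.0, "observed"),  # ratio 8
    ])
    f = srm_enrichment(result2, p2)
    assert f.factor == pytest.approx(5.0)
    assert f.basis == "srm_supplied"


def test_srm_enrichment_absent_protein_skipped():
    p = _enriched_params(protein_srm=["P1", "GHOST"], fmol_srm=[10.0, 1.0])
    result = _result([("P1", "Enr_1", 1e5, 30.0, "observed")])
    with pytest.warns(UserWarning, match="GHOST"):
        assert srm_enrichment(result, p).factor == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# absolute units
# ---------------------------------------------------------------------------

def test_unit_conversion_hand_arithmetic():
    """fmol_total, ng/µg and molecules/cell match hand computation to 1e-9."""
    p = ExperimentalParams(
        condition="C", sample_volume_ul=2.0, protein_conc_ug_per_ul=5.0,
        amount_ms_ug=5.0, cells_per_ml=1e7, total_culture_volume=10_000.0,
    )  # 10 µg total, 5 µg injected, 1e8 cells harvested
    result = _result([("P1", "C_1", 1e5, 10.0, "observed")])
    out = to_absolute(result, p, mol_weights={"P1": 50.0}).data.iloc[0]
    assert out["fmol_total"] == pytest.approx(20.0, rel=1e-9)
    assert out["ng_per_ug"] == pytest.approx(0.1, rel=1e-9)
    # 20 fmol in 1e8 cells: 20e-15 * N_A / 1e8 ~ 120.44 molecules per cell
    assert out["molecules_per_cell"] == pytest.approx(
        20e-15 * AVOGADRO / 1e8, rel=1e-9)
    assert out["molecules_per_cell"] == pytest.approx(1.2044e2, rel=1e-4)
    assert out["enrichment_corrected"] == False  # noqa: E712


def test_culture_volume_unit_switch():
    kw = dict(condition="C", sample_volume_ul=2.0, protein_conc_ug_per_ul=5.0,
              amount_ms_ug=5.0, cells_per_ml=1e7, total_culture_volume=10.0)
    assert ExperimentalParams(**kw).cells_total == pytest.approx(1e5)  # µL default
    assert ExperimentalParams(**kw, culture_volume_unit="mL").cells_total == (
        pytest.approx(1e8))


def test_missing_mol_weight_leaves_ng_per_ug_unset():
    p = ExperimentalParams(condition="C", sample_volume_ul=2.0,
                           protein_conc_ug_per_ul=5.0, amount_ms_ug=5.0)
    result = _result([("P1", "C_1", 1e5, 10.0, "observed"),
                      ("P2", "C_1", 1e5, 10.0, "observed")])
    with pytest.warns(UserWarning, match="molecular weight"):
        out = to_absolute(result, p, mol_weights={"P1": 50.0}).data
    assert np.isfinite(out.loc[out.protein_id == "P1", "ng_per_ug"]).all()
    assert out.loc[out.protein_id == "P2", "ng_per_ug"].isna().all()


def test_linearity_of_absolute_outputs():
    p = ExperimentalParams(
        condition="C", sample_volume_ul=3.0, protein_conc_ug_per_ul=4.0,
        amount_ms_ug=2.0, cells_per_ml=5e6, total_culture_volume=2000.0,
    )
    r1 = _result([("P1", "C_1", 1e5, 10.0, "observed")])
    r2 = _result([("P1", "C_1", 2e5, 20.0, "observed")])
    mw = {"P1": 42.0}
    a = to_absolute(r1, p, mol_weights=mw).data.iloc[0]
    b = to_absolute(r2, p, mol_weights=mw).data.iloc[0]
    for col in ("fmol_total", "ng_per_ug", "molecules_per_cell"):
        assert b[col] == pytest.approx(2 * a[col], rel=1e-12)


def test_factor_one_matches_uncorrected():
    p = _enriched_params(cells_per_ml=1e7, total_culture_volume=1e4)
    result = _result([("P1", "Enr_1", 1e5, 10.0, "observed")])
    unity = EnrichmentFactor(condition="Enr", factor=1.0, n_standards=3,
                             basis="spiked_standards")
    corrected = to_absolute(result, p, factors={"Enr": unity}).data.iloc[0]
    plain = to_absolute(result, p).data.iloc[0]
    assert corrected["molecules_per_cell"] == plain["molecules_per_cell"]
    assert corrected["enrichment_corrected"] and not plain["enrichment_corrected"]


def test_enrichment_round_trip_recovers_base_copy_numbers(tmp_path):
    """Per-cell copy numbers of the enriched condition, once corrected,
    match the unenriched condition within the noise tolerance."""
    spec = syn.SyntheticSpec(n_proteins=100, noise_sigma=0.1,
                             enrichment_factor=5.0, seed=23)
    ds = syn.make_enrichment_scenario(spec, tmp_path)
    rep = remove_flagged(read_report(ds.report_path))
    result = quantify_samples(rep, read_anchors(ds.anchors_path), "iBAQ")
    params = read_params(ds.params_path)
    p_enr = next(p for p in params if p.enrichment)
    factor = compute_enrichment(result, p_enr, read_standards(ds.standards_path))
    mw = dict(zip(rep.first_accessions(), rep.meta["mol_weight_kda"]))
    final = to_absolute(result, params, factors={p_enr.condition: factor},
                        mol_weights=mw).data
    native = final[final.protein_id.str.startswith("PROT")]
    per = native.pivot_table(index="protein_id", columns="condition",
                             values="molecules_per_cell")
    ratio = per["Enr"] / per["Base"]
    assert np.median(ratio) == pytest.approx(1.0, rel=0.2)


def test_unmatched_sample_raises():
    p = ExperimentalParams(condition="C", sample_volume_ul=2.0,
                           protein_conc_ug_per_ul=5.0, amount_ms_ug=5.0)
    result = _result([("P1", "Other_1", 1e5, 10.0, "observed")])
    with pytest.raises(ValueError, match="no parameter row"):
        to_absolute(result, p)
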