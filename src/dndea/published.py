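"""Published reference score tables for China's provincial two-stage panel.

Ships the per-province stage efficiency scores (production stage and health
stage, 2013-2017) and the regional per-variable efficiency averages as
reported for the 31 provincial administrative regions, grouped in the
National Bureau of Statistics four-region partition. The underlying
provincial yearbook observations are not deposited anywhere, so these score
tables are the only public quantities the regional analytics (totals,
ranks, regional means, growth rates, rank-based region comparison) can be
demonstrated and checked on.
"""

from __future__ import annotations

import io

import pandas as pd

# province, region, then stage1/stage2 score pairs for 2013..2017
_STAGE_SCORES_CSV = """\
dmu,region,s1_2013,s2_2013,s1_2014,s2_2014,s1_2015,s2_2015,s1_2016,s2_2016,s1_2017,s2_2017
Beijing,eastern,1,0.2871,1,0.3494,1,0.4739,1,1,1,1
Fujian,eastern,0.4835,0.7017,0.6203,0.6646,0.626,0.4966,0.5186,0.2285,0.545,0.2381
Guangdong,eastern,1,1,1,0.6453,1,0.427,1,1,1,1
Hainan,eastern,0.3612,0.4612,0.815,1,0.4201,0.231,0.4097,0.1696,0.4213,0.2046
Hebei,eastern,1,1,0.9029,1,0.9451,1,0.5861,0.2642,0.8697,0.1747
Jiangsu,eastern,0.4391,0.4095,0.5582,0.4002,0.6008,0.3401,0.616,0.1791,0.669,0.1608
Shandong,eastern,0.5594,0.2688,0.6449,0.2716,0.653,0.1855,0.6686,0.2058,0.6878,0.174
Shanghai,eastern,1,1,1,0.3407,1,0.9894,1,1,1,1
Tianjin,eastern,1,0.4678,1,0.301,1,0.3384,1,0.5766,1,0.4976
Zhejiang,eastern,0.6236,1,0.6964,1,0.6865,1,0.7959,0.4886,0.7943,0.5673
Anhui,central,0.3566,0.506,0.4067,0.344,0.4328,0.2174,0.4151,0.1005,0.4393,0.1035
Henan,central,0.3338,0.2216,0.4306,0.1919,0.4255,0.1337,0.427,0.1987,0.4396,0.2423
Hubei,central,0.5717,1,0.5308,0.5579,0.6856,1,0.4783,0.2356,0.4936,0.1984
Hunan,central,0.7351,1,0.8538,1,1,1,0.6595,0.4462,0.6348,0.3246
Jiangxi,central,0.457,0.9139,0.461,0.4775,0.5983,1,0.4067,0.2295,0.5228,0.1781
Shanxi,central,0.5884,0.5541,0.4178,0.2427,0.4215,0.1715,0.4008,0.13,0.4341,0.1088
Inner Mongolia,western,1,0.3692,1,0.4396,1,0.3049,1,0.1657,1,0.1498
Xinjiang,western,0.2596,0.2553,0.421,0.1463,0.5404,1,0.3695,0.1401,0.5409,0.1254
Yunnan,western,0.4943,1,0.5056,0.4632,0.7778,0.7551,1,1,0.4807,0.2024
Ningxia,western,0.3878,0.2204,0.4678,0.1283,0.63,0.6245,0.6679,0.0995,0.546,0.0856
Qinghai,western,0.3906,0.3958,0.4461,0.1909,0.6857,1,0.4827,0.1072,0.8024,0.1158
Shaanxi,western,0.4258,0.1695,0.4719,0.2215,0.4573,0.1498,0.4637,0.231,0.4811,0.1444
Sichuan,western,0.5857,0.7876,0.4734,0.2778,0.5496,0.3553,0.4519,0.3197,0.4739,0.1651
Chongqing,western,0.5432,1,0.6834,1,0.732,0.7598,0.7812,0.394,1,1
Gansu,western,0.2745,0.1377,0.402,0.1298,0.6032,1,0.6411,0.1106,0.4391,0.1497
Guangxi,western,0.471,1,0.5032,0.3744,0.6071,0.9217,0.4169,0.1789,0.3938,0.1312
Guizhou,western,0.467,0.903,0.4743,0.5264,0.6053,1,0.4542,0.3746,0.4168,0.0984
Tibet,western,1,0.089786,1,0.086604,1,0.207483,1,1,1,0.472495
Jilin,northeastern,0.4652,0.2895,0.7567,0.5744,0.844,0.1657,0.7493,0.6306,0.4775,0.2549
Heilongjiang,northeastern,0.3295,0.2163,0.8138,0.6443,0.4963,0.0908,0.4633,0.1537,0.6595,0.1685
Liaoning,northeastern,0.4981,0.4174,0.5605,0.5957,0.7302,0.3832,1,0.5179,0.7021,0.2385
"""

# regional average efficiency of each model variable, per year
_VARIABLE_EFFICIENCY_CSV = """\
variable,region,2013,2014,2015,2016,2017
water_consumption,eastern,0.6602,0.7517,0.6675,0.6224,0.6878
water_consumption,central,0.4953,0.3102,0.4536,0.2219,0.2652
water_consumption,western,0.4755,0.4075,0.5555,0.5400,0.4855
water_consumption,northeastern,0.1952,0.6017,0.4370,0.5637,0.3344
labor,eastern,0.9271,0.9063,0.9080,0.8968,0.9064
labor,central,0.7264,0.7718,0.7431,0.7174,0.7226
labor,western,0.7227,0.7415,0.8035,0.7760,0.7687
labor,northeastern,0.8420,0.8501,0.8620,0.8078,0.7951
treatment_expense,eastern,0.7041,0.6574,0.5073,0.4759,0.4730
treatment_expense,central,0.7071,0.6272,0.5302,0.2059,0.1193
treatment_expense,western,0.5337,0.3719,0.6999,0.3560,0.2568
treatment_expense,northeastern,0.5301,0.9848,0.2018,0.5200,0.2593
cod,eastern,0.8538,0.9249,0.8561,0.7475,0.7702
cod,central,0.7588,0.4972,0.7124,0.3799,0.4088
cod,western,0.7634,0.6117,0.8602,0.6535,0.6484
cod,northeastern,0.2740,0.6246,0.5203,0.7704,0.5885
wastewater,eastern,0.7192,0.8361,0.8286,0.8021,0.8431
wastewater,central,0.5607,0.5696,0.662,0.5572,0.6272
wastewater,western,0.6742,0.6628,0.8343,0.7374,0.7783
wastewater,northeastern,0.6916,0.8165,0.8147,0.8653,0.7684
treatment_capacity,eastern,0.9214,0.7925,0.7888,0.8961,0.8063
treatment_capacity,central,1,1,0.964,0.8444,0.8233
treatment_capacity,western,0.8511,0.7299,0.8281,0.6736,0.5043
treatment_capacity,northeastern,1,1,0.6594,1,0.7406
water_diseases,eastern,0.6655,0.6261,0.7677,0.4435,0.5054
water_diseases,central,0.7802,0.4043,0.6246,0.3995,0.3834
water_diseases,western,0.5710,0.4644,0.8832,0.3833,0.3410
water_diseases,northeastern,0.3381,0.3378,0.8390,0.0296,0.0584
"""

YEARS = ["2013", "2014", "2015", "2016", "2017"]


def published_stage_scores() -> pd.DataFrame:
    """Long frame: dmu, region, year, stage1, stage2 for all 31 provinces."""
    wide = pd.read_csv(io.StringIO(_STAGE_SCORES_CSV))
    rows = []
    for _, r in wide.iterrows():
        for y in YEARS:
            rows.append({
                "dmu": r["dmu"], "region": r["region"], "year": y,
                "stage1": float(r[f"s1_{y}"]), "stage2": float(r[f"s2_{y}"]),
            })
    return pd.DataFrame(rows)


def published_variable_efficiencies() -> pd.DataFrame:
    """Long frame: variable, region, year, value (regional averages)."""
    wide = pd.read_csv(io.StringIO(_VARIABLE_EFFICIENCY_CSV))
    return wide.melt(
        id_vars=["variable", "region"], var_name="year", value_name="value"
    )
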