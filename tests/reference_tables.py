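"""Published reference values from the NSW 2010–2014 linked-data
cancer-incidence enhancement analysis.

Each count row is (stratum label, registry count, then per method
(enhanced count, printed relative increase %)); each rate row is the
same shape with age-standardised rates per 100,000.  Method order is
ever-reported, most-recent, weight-of-evidence, multi-stage median.
These printed values serve as worked-example inputs for the arithmetic
the package implements; they are not recomputable from microdata here.
"""

TOTAL_CASES = 204_948
UNKNOWN_STATUS_CASES = 28_572
REGISTRY_ABORIGINAL_CASES = 2703
METHOD_TOTALS = {"ever": 4184, "most_recent": 3257,
                 "weight_of_evidence": 3580, "multi_stage_median": 3583}
METHOD_TOTAL_PCT = {"ever": 2.0, "most_recent": 1.6,
                    "weight_of_evidence": 1.7, "multi_stage_median": 1.7}
REGISTRY_PCT = 1.3
UNKNOWN_PCT = 13.9
WOE_CHANGED = 877
WOE_FROM_NON_ABORIGINAL = 651
WOE_FROM_UNKNOWN = 226

# ---- counts by stratum: (label, base, (ever n, %), (mr n, %), (woe n, %), (msm n, %))
COUNT_ROWS = [
    ("female", 1329, (1920, 44.5), (1575, 18.5), (1689, 27.1), (1701, 28.0)),
    ("male", 1374, (2264, 64.8), (1682, 22.4), (1891, 37.6), (1882, 37.0)),
    ("age 0-14", 49, (61, 24.5), (54, 10.2), (57, 16.3), (56, 14.3)),
    ("age 15-24", 47, (68, 44.7), (61, 29.8), (62, 31.9), (64, 36.2)),
    ("age 25-34", 86, (143, 66.3), (120, 39.5), (128, 48.8), (130, 51.2)),
    ("age 35-44", 224, (322, 43.8), (276, 23.2), (289, 29.0), (293, 30.8)),
    ("age 45-54", 521, (727, 39.5), (627, 20.3), (661, 26.9), (675, 29.6)),
    ("age 55-64", 714, (1076, 50.7), (867, 21.4), (949, 32.9), (945, 32.4)),
    ("age 65-74", 660, (1058, 60.3), (785, 18.9), (878, 33.0), (876, 32.7)),
    ("age 75-84", 332, (570, 71.7), (388, 16.9), (451, 35.8), (447, 34.6)),
    ("age 85+", 70, (159, 127.1), (79, 12.9), (105, 50.0), (97, 38.6)),
    ("year 2010", 497, (766, 54.1), (594, 19.5), (664, 33.6), (661, 33.0)),
    ("year 2011", 532, (830, 56.0), (639, 20.1), (704, 32.3), (705, 32.5)),
    ("year 2012", 535, (836, 56.3), (646, 20.7), (710, 32.7), (712, 33.1)),
    ("year 2013", 569, (851, 49.6), (683, 20.0), (745, 30.9), (747, 31.3)),
    ("year 2014", 570, (901, 58.1), (695, 21.9), (757, 32.8), (758, 33.0)),
    ("skin", 91, (284, 212.1), (177, 94.5), (212, 133.0), (216, 137.4)),
    ("head and neck", 145, (205, 41.4), (171, 17.9), (186, 28.3), (184, 26.9)),
    ("upper gastrointestinal", 340, (442, 30.0), (367, 7.9), (394, 15.9), (392, 15.3)),
    ("colorectal", 299, (442, 47.8), (356, 19.1), (385, 28.8), (379, 26.8)),
    ("respiratory", 430, (553, 28.6), (464, 7.9), (508, 18.1), (502, 16.7)),
    ("bone and connective tissue", 25, (34, 36.0), (29, 16.0), (32, 28.0), (33, 32.0)),
    ("breast", 314, (472, 50.3), (391, 24.5), (413, 31.5), (420, 33.8)),
    ("gynaecological", 179, (249, 39.1), (207, 15.6), (222, 24.0), (223, 24.6)),
    ("urogenital", 416, (803, 93.0), (547, 31.5), (627, 50.7), (633, 52.2)),
    ("eye and neurological", 45, (68, 51.1), (51, 13.3), (56, 24.4), (57, 26.7)),
    ("thyroid and endocrine", 64, (109, 70.3), (81, 26.6), (93, 45.3), (94, 46.9)),
    ("lymphohaematopoietic", 258, (401, 55.4), (313, 21.3), (344, 33.3), (343, 32.9)),
    ("ill-defined and unknown", 97, (122, 25.8), (103, 6.2), (108, 11.3), (107, 10.3)),
    ("localised", 819, (1467, 79.1), (1086, 32.6), (1209, 47.6), (1212, 48.0)),
    ("regional", 668, (964, 44.3), (767, 14.8), (857, 28.3), (850, 27.2)),
    ("distant", 661, (783, 18.5), (686, 3.8), (713, 7.9), (713, 7.9)),
    ("spread unknown", 555, (970, 74.8), (718, 29.4), (801, 44.3), (808, 45.6)),
    ("major cities", 1206, (1998, 65.7), (1472, 22.1), (1639, 35.9), (1633, 35.4)),
    ("inner regional", 831, (1277, 53.7), (1001, 20.5), (1098, 32.1), (1109, 33.5)),
    ("outer regional", 530, (738, 39.2), (620, 17.0), (678, 27.9), (675, 27.4)),
    ("remote/very remote", 136, (171, 25.7), (164, 20.6), (165, 21.3), (166, 22.1)),
    ("seifa q1", 131, (280, 113.7), (157, 19.8), (194, 48.1), (195, 48.9)),
    ("seifa q2", 352, (596, 69.3), (441, 25.3), (487, 38.4), (485, 37.8)),
    ("seifa q3", 474, (785, 65.6), (580, 22.4), (650, 37.1), (654, 38.0)),
    ("seifa q4", 843, (1219, 44.6), (1004, 19.1), (1082, 28.4), (1087, 28.9)),
    ("seifa q5", 903, (1304, 44.4), (1075, 19.0), (1167, 29.2), (1162, 28.7)),
]

# ---- ASRs per 100,000: (label, base ASR, (ever, %), (mr, %), (woe, %), (msm, %))
RATE_ROWS = [
    ("all cancers persons", 559.9, (918.0, 64.0), (667.9, 19.3), (753.7, 34.6), (748.0, 33.6)),
    ("all cancers females", 504.6, (750.5, 48.7), (588.5, 16.6), (642.7, 27.4), (645.2, 27.9)),
    ("all cancers males", 629.4, (1135.3, 80.4), (766.7, 21.8), (894.1, 42.1), (875.6, 39.1)),
    ("colorectal persons", 63.9, (104.5, 63.5), (77.7, 21.6), (86.3, 35.1), (84.1, 31.6)),
    ("colorectal females", 60.7, (87.3, 43.8), (70.5, 16.1), (76.2, 25.5), (76.7, 26.4)),
    ("colorectal males", 67.3, (127.7, 89.7), (86.3, 28.2), (99.7, 48.1), (92.7, 37.7)),
    ("lung persons", 95.4, (125.9, 32.0), (104.2, 9.2), (114.6, 20.1), (112.5, 17.9)),
    ("lung females", 83.9, (103.8, 23.7), (89.8, 7.0), (97.5, 16.2), (96.8, 15.4)),
    ("lung males", 110.5, (155.8, 41.0), (123.3, 11.6), (137.4, 24.3), (133.3, 20.6)),
    ("melanoma persons", 16.7, (57.3, 243.1), (28.4, 70.1), (37.8, 126.3), (36.8, 120.4)),
    ("melanoma females", 11.5, (36.0, 213.0), (22.1, 92.2), (25.0, 117.4), (27.2, 136.5)),
    ("melanoma males", 23.3, (85.0, 264.8), (36.1, 54.9), (53.5, 129.6), (47.7, 104.7)),
    ("breast females", 105.2, (161.1, 53.1), (130.9, 24.4), (140.0, 33.1), (142.1, 35.1)),
    ("cervix", 14.7, (19.4, 32.0), (16.3, 10.9), (16.7, 13.6), (16.9, 15.0)),
    ("prostate", 126.1, (281.8, 123.5), (172.7, 37.0), (205.2, 62.7), (203.6, 61.5)),
]

METHODS = ("ever", "most_recent", "weight_of_evidence", "multi_stage_median")
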