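id_label,diameter_measured_mm,diameter_estimated_mm,lifespan_days,oi_mean_hu,oi_sd_hu,corrected_mean_hu,cv_mean_hu,dv_max_hu,quality_flags
1.1,18,17.96,1051,-79,226,345,-425,1606,
1.2,20,20.5,1420,623,281,754,-209,2006,
1.3,20,19.96,1037,496,222,496,-344,3071,
1.4,18,17.66,1361,566,337,713,-179,1920,
1.5,20,20.5,1040,-42,101,434,-458,1476,
1.6,18,16.26,2493,391,383,598,-147,1664,
1.7,20,19.68,1911,579,304,825,-331,1884,
1.8,20,19.58,1031,38,143,480,-446,1588,
1.9,20,20.14,776,371,121,411,-87,2162,
1.10,20,20.1,718,200,85,397,-198,1828,
1.11,18,17.92,1196,350,105,360,-39,2146,
1.12,20,20.1,1466,852,281,939,-104,1939,
1.13,18,17.86,1831,773,383,784,-187,2273,
1.14,18,17.4,317,308,128,417,-131,1995,
1.15,18,17.88,1425,750,303,891,-127,1848,
1.16,20,20.08,79,823,376,779,-131,2329,
1.17,18,18.56,2151,728,361,790,-166,2106,
1.18,18,17.92,2427,775,37,696,-78,2384,
1.19,20,19.78,1237,302,102,424,-148,1995,
1.20,20,20.26,1202,132,143,321,-212,1958,
1.21,20,19.62,213,1432,521,786,326,3150,
1.22,18,17.62,2219,414,253,695,-285,1736,
1.23,20,19.72,1140,131,11,363,-228,1773,
1.24,18,17.96,1903,729,388,810,-166,2051,
1.25,16,17.78,2636,729,407,711,-77,2200,
1.26,10,19.66,801,390,112,387,-29,2162,suspect_diameter
1.27,20,20.4,452,935,397,702,78,2532,
1.28,20,20.7,1515,871,322,825,-57,2200,
1.29,20,19.78,910,865,131,378,340,3150,
1.30,20,20.4,2093,893,279,807,40,2161,
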