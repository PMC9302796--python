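"""Externally reported Monte Carlo summaries for the benchmark simulation design.

These are the reference Mean/SE/RMSE values (1000 replicates, true parameters
beta = (3, -5), psi = (1.5, 0.1, 5.5)) that the replication harness is the
machine twin of: the correctly specified AR(1) study (T1) and the three
misspecification studies at rho = 0.1 / 0.5 / 0.95 (T2-T4).  Each block maps
parameter name -> (mean_25, se_25, rmse_25, mean_500, se_500, rmse_500),
where the suffix is the sample size.
"""

PARAMS = ("beta0", "beta1", "psi1", "psi2", "psi3")

# (table, method, structure, rho) -> {param: 6-tuple}
REFERENCE_BLOCKS = {
    ("T1", "qif", "ar1", 0.1): {
        "beta0": (3.0442, 0.3685, 0.3712, 3.0596, 0.3803, 0.3850),
        "beta1": (-4.9017, 0.1962, 0.2195, -4.8988, 0.2135, 0.2362),
        "psi1": (1.5558, 0.3601, 0.3644, 1.5561, 0.3894, 0.3934),
        "psi2": (0.1956, 0.2691, 0.2856, 0.2037, 0.2665, 0.2859),
        "psi3": (5.6546, 0.2147, 0.2646, 5.6269, 0.2171, 0.2515),
    },
    ("T1", "rqif", "ar1", 0.1): {
        "beta0": (3.0528, 0.2974, 0.3020, 3.0324, 0.3120, 0.3137),
        "beta1": (-4.9154, 0.1731, 0.1926, -4.9166, 0.1656, 0.1854),
        "psi1": (1.5316, 0.3404, 0.3419, 1.5333, 0.3342, 0.3358),
        "psi2": (0.2168, 0.2530, 0.2786, 0.2400, 0.2625, 0.2975),
        "psi3": (5.6035, 0.1928, 0.2188, 5.6036, 0.1999, 0.2252),
    },
    ("T1", "qif", "ar1", 0.5): {
        "beta0": (3.0311, 0.3521, 0.3535, 3.0292, 0.3428, 0.3441),
        "beta1": (-4.9223, 0.1916, 0.2067, -4.9212, 0.1961, 0.2113),
        "psi1": (1.6086, 0.3687, 0.3844, 1.5549, 0.3340, 0.3384),
        "psi2": (0.2245, 0.3203, 0.3436, 0.2323, 0.2759, 0.3060),
        "psi3": (5.6301, 0.2163, 0.2524, 5.6416, 0.2295, 0.2697),
    },
    ("T1", "rqif", "ar1", 0.5): {
        "beta0": (3.0352, 0.3101, 0.3121, 3.0448, 0.2970, 0.3003),
        "beta1": (-4.9165, 0.1789, 0.1974, -4.9266, 0.1720, 0.1870),
        "psi1": (1.5513, 0.3242, 0.3282, 1.5363, 0.3446, 0.3465),
        "psi2": (0.2155, 0.2656, 0.2896, 0.2428, 0.2522, 0.2899),
        "psi3": (5.6063, 0.2031, 0.2292, 5.6026, 0.1939, 0.2194),
    },
    ("T1", "qif", "ar1", 0.95): {
        "beta0": (3.0824, 0.3606, 0.3699, 3.0514, 0.3118, 0.3160),
        "beta1": (-4.8987, 0.2140, 0.2367, -4.9067, 0.2045, 0.2248),
        "psi1": (1.5349, 0.3998, 0.4013, 1.5637, 0.3731, 0.3785),
        "psi2": (0.2027, 0.2925, 0.3100, 0.2107, 0.2674, 0.2894),
        "psi3": (5.6263, 0.2216, 0.2551, 5.6302, 0.2201, 0.2557),
    },
    ("T1", "rqif", "ar1", 0.95): {
        "beta0": (3.0503, 0.2901, 0.2944, 3.0339, 0.3014, 0.3033),
        "beta1": (-4.9251, 0.1698, 0.1856, -4.9098, 0.1679, 0.1907),
        "psi1": (1.5355, 0.3352, 0.3371, 1.5332, 0.3613, 0.3628),
        "psi2": (0.2267, 0.2618, 0.2908, 0.2281, 0.2720, 0.3007),
        "psi3": (5.6058, 0.1846, 0.2127, 5.6060, 0.1979, 0.2245),
    },
    ("T2", "qif", "exchangeable", 0.1): {
        "beta0": (3.0645, 0.3672, 0.3728, 3.0790, 0.3613, 0.3699),
        "beta1": (-4.8821, 0.2071, 0.2383, -4.8961, 0.2096, 0.2340),
        "psi1": (1.5157, 0.4074, 0.4077, 1.5514, 0.3795, 0.3830),
        "psi2": (0.1980, 0.2941, 0.3100, 0.1909, 0.2613, 0.2767),
        "psi3": (5.6276, 0.1952, 0.2332, 5.6270, 0.2277, 0.2607),
    },
    ("T2", "qif", "unspecified", 0.1): {
        "beta0": (2.9806, 0.4761, 0.4765, 2.9593, 0.4881, 0.4898),
        "beta1": (-4.9094, 0.2694, 0.2843, -4.9037, 0.2389, 0.2576),
        "psi1": (1.5900, 0.5022, 0.5103, 1.5900, 0.5650, 0.5721),
        "psi2": (0.2376, 0.3304, 0.3579, 0.2361, 0.2575, 0.2913),
        "psi3": (5.6526, 0.2461, 0.2896, 5.6581, 0.2357, 0.2838),
    },
    ("T2", "rqif", "exchangeable", 0.1): {
        "beta0": (3.0552, 0.3411, 0.3455, 3.0373, 0.3554, 0.3573),
        "beta1": (-4.9108, 0.1659, 0.1883, -4.9051, 0.1643, 0.1897),
        "psi1": (1.5284, 0.3452, 0.3464, 1.5199, 0.3650, 0.3656),
        "psi2": (0.2122, 0.2545, 0.2781, 0.1989, 0.2618, 0.2799),
        "psi3": (5.5959, 0.2063, 0.2275, 5.6178, 0.1911, 0.2245),
    },
    ("T2", "rqif", "unspecified", 0.1): {
        "beta0": (3.0111, 0.4069, 0.4071, 2.9980, 0.3949, 0.3949),
        "beta1": (-4.9116, 0.1951, 0.2142, -4.9123, 0.1928, 0.2119),
        "psi1": (1.5272, 0.4894, 0.4902, 1.5415, 0.5086, 0.5103),
        "psi2": (0.2339, 0.2960, 0.3249, 0.2326, 0.2512, 0.2840),
        "psi3": (5.6149, 0.2122, 0.2413, 5.6203, 0.1876, 0.2228),
    },
    ("T3", "qif", "exchangeable", 0.5): {
        "beta0": (3.0382, 0.4092, 0.4110, 3.0596, 0.4076, 0.4119),
        "beta1": (-4.8863, 0.1930, 0.2240, -4.8863, 0.1998, 0.2298),
        "psi1": (1.5769, 0.3343, 0.3430, 1.5301, 0.3806, 0.3818),
        "psi2": (0.1984, 0.2691, 0.2865, 0.2049, 0.2762, 0.2954),
        "psi3": (5.6305, 0.2191, 0.2550, 5.6194, 0.1988, 0.2319),
    },
    ("T3", "qif", "unspecified", 0.5): {
        "beta0": (3.0109, 0.4180, 0.4181, 3.0342, 0.4024, 0.4038),
        "beta1": (-4.9027, 0.2338, 0.2533, -4.9305, 0.2197, 0.2304),
        "psi1": (1.5958, 0.4666, 0.4764, 1.6050, 0.5100, 0.5207),
        "psi2": (0.2211, 0.3208, 0.3429, 0.2631, 0.2868, 0.3300),
        "psi3": (5.6165, 0.2055, 0.2363, 5.5904, 0.2032, 0.2224),
    },
    ("T3", "rqif", "exchangeable", 0.5): {
        "beta0": (3.0594, 0.3355, 0.3407, 3.0422, 0.3355, 0.3382),
        "beta1": (-4.9105, 0.1606, 0.1838, -4.9146, 0.1771, 0.1966),
        "psi1": (1.5171, 0.3443, 0.3447, 1.5107, 0.3758, 0.3759),
        "psi2": (0.2007, 0.2496, 0.2691, 0.2083, 0.2561, 0.2781),
        "psi3": (5.6083, 0.1878, 0.2168, 5.6162, 0.1998, 0.2311),
    },
    ("T3", "rqif", "unspecified", 0.5): {
        "beta0": (3.0182, 0.4152, 0.4156, 2.9904, 0.4173, 0.4174),
        "beta1": (-4.9158, 0.1944, 0.2118, -4.9178, 0.1868, 0.2041),
        "psi1": (1.5059, 0.4972, 0.4972, 1.5257, 0.5301, 0.5307),
        "psi2": (0.2308, 0.2858, 0.3143, 0.2471, 0.2620, 0.3005),
        "psi3": (5.6149, 0.2098, 0.2392, 5.6232, 0.1913, 0.2275),
    },
    ("T4", "qif", "exchangeable", 0.95): {
        "beta0": (3.0917, 0.3967, 0.4071, 3.0433, 0.3566, 0.3593),
        "beta1": (-4.9110, 0.2219, 0.2391, -4.8956, 0.1836, 0.2112),
        "psi1": (1.5109, 0.3888, 0.3890, 1.5925, 0.3413, 0.3536),
        "psi2": (0.2113, 0.2789, 0.3003, 0.2072, 0.2833, 0.3030),
        "psi3": (5.6337, 0.2271, 0.2635, 5.6022, 0.1977, 0.2226),
    },
    ("T4", "qif", "unspecified", 0.95): {
        "beta0": (3.0447, 0.4625, 0.4646, 3.0129, 0.4968, 0.4970),
        "beta1": (-4.8935, 0.1912, 0.2189, -4.9421, 0.2372, 0.2442),
        "psi1": (1.5760, 0.4772, 0.4832, 1.5813, 0.4911, 0.4978),
        "psi2": (0.2113, 0.2811, 0.3023, 0.2701, 0.3556, 0.3941),
        "psi3": (5.6389, 0.2353, 0.2732, 5.6423, 0.2583, 0.2948),
    },
    ("T4", "rqif", "exchangeable", 0.95): {
        "beta0": (3.0282, 0.3621, 0.3632, 3.0463, 0.3371, 0.3402),
        "beta1": (-4.8960, 0.1728, 0.2016, -4.9026, 0.1741, 0.1995),
        "psi1": (1.5156, 0.3482, 0.3485, 1.5032, 0.3687, 0.3687),
        "psi2": (0.2070, 0.2559, 0.2774, 0.2198, 0.2571, 0.2836),
        "psi3": (5.6102, 0.2042, 0.2320, 5.5970, 0.1978, 0.2203),
    },
    ("T4", "rqif", "unspecified", 0.95): {
        "beta0": (3.0027, 0.4507, 0.4507, 2.9941, 0.3957, 0.3957),
        "beta1": (-4.9160, 0.2012, 0.2180, -4.9011, 0.1739, 0.2000),
        "psi1": (1.5389, 0.4213, 0.4231, 1.5199, 0.4691, 0.4696),
        "psi2": (0.2321, 0.2768, 0.3067, 0.2415, 0.2448, 0.2827),
        "psi3": (5.6229, 0.2122, 0.2452, 5.6142, 0.1927, 0.2240),
    },
}

TRUTH = {"beta0": 3.0, "beta1": -5.0, "psi1": 1.5, "psi2": 0.1, "psi3": 5.5}


def iter_rows():
    """Yield (key, param, n, mean, se, rmse) over every transcribed table row."""
    for key, block in REFERENCE_BLOCKS.items():
        for param, vals in block.items():
            yield key, param, 25, vals[0], vals[1], vals[2]
            yield key, param, 500, vals[3], vals[4], vals[5]
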