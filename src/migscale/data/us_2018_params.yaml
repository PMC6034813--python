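# Published scaling coefficients for US metropolitan migration
# (385 MSAs; log-log OLS fits, intercepts are natural logarithms of alpha).
name: us_2018_params
population_range: [50000, 20000000]
n_cities: 385
countryside_population: 51000000
p_countryside_leave: 0.0322

outflow:
  leave_city:
    {beta: 0.8829, se_beta: 0.0147, log_alpha: -1.7863, se_log_alpha: 0.1867, adj_r2: 0.9033}
  to_countryside:
    {beta: 0.6846, se_beta: 0.0273, log_alpha: -0.7214, se_log_alpha: 0.3464, adj_r2: 0.6199}
  destination_by_origin_size:
    - {kind: below, threshold: 200000,   beta: 0.8060, se_beta: 0.0263, log_alpha: -2.8555,  se_log_alpha: 0.3325, adj_r2: 0.7101}
    - {kind: below, threshold: 300000,   beta: 0.8199, se_beta: 0.0232, log_alpha: -2.6039,  se_log_alpha: 0.2949, adj_r2: 0.7636}
    - {kind: below, threshold: 400000,   beta: 0.8171, se_beta: 0.0222, log_alpha: -2.285,   se_log_alpha: 0.2811, adj_r2: 0.7794}
    - {kind: below, threshold: 500000,   beta: 0.8224, se_beta: 0.0206, log_alpha: -2.1614,  se_log_alpha: 0.2607, adj_r2: 0.8061}
    - {kind: below, threshold: 1000000,  beta: 0.8363, se_beta: 0.0175, log_alpha: -1.9163,  se_log_alpha: 0.2224, adj_r2: 0.8554}
    - {kind: below, threshold: 3000000,  beta: 0.8609, se_beta: 0.0159, log_alpha: -1.8352,  se_log_alpha: 0.2021, adj_r2: 0.8863}
    - {kind: below, threshold: 5000000,  beta: 0.8689, se_beta: 0.0157, log_alpha: -1.8189,  se_log_alpha: 0.1999, adj_r2: 0.8877}
    - {kind: above, threshold: 1000000,  beta: 0.9570, se_beta: 0.0211, log_alpha: -3.4759,  se_log_alpha: 0.2674, adj_r2: 0.8426}
    - {kind: above, threshold: 3000000,  beta: 1.0073, se_beta: 0.0307, log_alpha: -4.8421,  se_log_alpha: 0.3891, adj_r2: 0.7369}
    - {kind: above, threshold: 5000000,  beta: 1.0499, se_beta: 0.0337, log_alpha: -5.8437,  se_log_alpha: 0.4271, adj_r2: 0.7163}
    - {kind: above, threshold: 8000000,  beta: 1.1688, se_beta: 0.0506, log_alpha: -8.5108,  se_log_alpha: 0.6408, adj_r2: 0.5814}
    - {kind: above, threshold: 10000000, beta: 1.2984, se_beta: 0.0619, log_alpha: -10.6921, se_log_alpha: 0.7855, adj_r2: 0.5327}

inflow:
  from_countryside:
    {beta: 0.5971, se_beta: 0.0342, log_alpha: 0.4299, se_log_alpha: 0.4331, adj_r2: 0.4421}
  origin_by_size:
    - {kind: below, threshold: 200000,   beta: 0.7997, se_beta: 0.0299, log_alpha: -2.7992, se_log_alpha: 0.3799, adj_r2: 0.6492}
    - {kind: below, threshold: 300000,   beta: 0.8036, se_beta: 0.0277, log_alpha: -2.4173, se_log_alpha: 0.3507, adj_r2: 0.6869}
    - {kind: below, threshold: 400000,   beta: 0.8110, se_beta: 0.0262, log_alpha: -2.2685, se_log_alpha: 0.3315, adj_r2: 0.7144}
    - {kind: below, threshold: 500000,   beta: 0.8159, se_beta: 0.0245, log_alpha: -2.1231, se_log_alpha: 0.3103, adj_r2: 0.7429}
    - {kind: below, threshold: 1000000,  beta: 0.8331, se_beta: 0.0211, log_alpha: -1.9238, se_log_alpha: 0.2678, adj_r2: 0.8018}
    - {kind: below, threshold: 3000000,  beta: 0.8437, se_beta: 0.0203, log_alpha: -1.6504, se_log_alpha: 0.2570, adj_r2: 0.8184}
    - {kind: below, threshold: 5000000,  beta: 0.8521, se_beta: 0.0202, log_alpha: -1.6248, se_log_alpha: 0.2555, adj_r2: 0.8230}
    - {kind: above, threshold: 1000000,  beta: 0.9193, se_beta: 0.0251, log_alpha: -2.8957, se_log_alpha: 0.3177, adj_r2: 0.7777}
    - {kind: above, threshold: 3000000,  beta: 0.9776, se_beta: 0.0346, log_alpha: -4.2905, se_log_alpha: 0.4390, adj_r2: 0.6744}
    - {kind: above, threshold: 5000000,  beta: 1.0184, se_beta: 0.0382, log_alpha: -5.2401, se_log_alpha: 0.4851, adj_r2: 0.648}
    - {kind: above, threshold: 8000000,  beta: 1.1180, se_beta: 0.0460, log_alpha: -7.4146, se_log_alpha: 0.5834, adj_r2: 0.6053}
    - {kind: above, threshold: 10000000, beta: 1.2539, se_beta: 0.0574, log_alpha: -9.6531, se_log_alpha: 0.7272, adj_r2: 0.5538}

international:
  All:      {beta: 1.1884, se_beta: 0.0339, log_alpha: -7.9153,  se_log_alpha: 0.4305, adj_r2: 0.761}
  Africa:   {beta: 1.5794, se_beta: 0.0728, log_alpha: -16.5087, se_log_alpha: 0.9230, adj_r2: 0.55}
  Asia:     {beta: 1.2207, se_beta: 0.0519, log_alpha: -9.3143,  se_log_alpha: 0.6588, adj_r2: 0.5891}
  Americas: {beta: 1.2808, se_beta: 0.0424, log_alpha: -10.5175, se_log_alpha: 0.5374, adj_r2: 0.7036}
  Europe:   {beta: 1.2264, se_beta: 0.0515, log_alpha: -10.2535, se_log_alpha: 0.6530, adj_r2: 0.5956}
  Oceania:  {beta: 1.3312, se_beta: 0.0747, log_alpha: -14.5814, se_log_alpha: 0.9465, adj_r2: 0.452}
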