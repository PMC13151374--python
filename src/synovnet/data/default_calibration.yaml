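# Default generator calibration: published group-level summaries for the
# 108-patient synovial-fluid cohort. Per marker: [mean, ci_half, min, max];
# ci_half is the half-width of the 95% CI of the group mean.
# Units: cd45_abs in 1e9 cells/l, the rest in % of CD45+ cells.
mode: calibrated
groups:
  - group_label: PJI
    n: 16
    markers:
      cd45_abs: [37.3, 24.9, 0.1, 149.1]
      lym_pct: [17.0, 12.6, 0.5, 67.4]
      mon_mphi_pct: [11.5, 5.3, 0.5, 27.2]
      neu_pct: [70.7, 16.8, 4.2, 98.1]
  - group_label: LG-PJI
    n: 8
    markers:
      cd45_abs: [2.4, 2.0, 0.5, 6.3]
      lym_pct: [8.3, 3.9, 3.1, 15.3]
      mon_mphi_pct: [12.5, 8.7, 1.0, 28.8]
      neu_pct: [78.2, 10.5, 59.4, 92.2]
  - group_label: OL/AL
    n: 20
    markers:
      cd45_abs: [1.2, 1.0, 0.1, 9.7]
      lym_pct: [46.5, 11.1, 6.4, 89.1]
      mon_mphi_pct: [32.9, 10.6, 6.0, 77.9]
      neu_pct: [19.5, 6.6, 2.5, 47.0]
  - group_label: OA-INF
    n: 28
    markers:
      cd45_abs: [17.3, 6.4, 0.2, 59.3]
      lym_pct: [7.6, 3.2, 0.2, 29.5]
      mon_mphi_pct: [13.7, 5.0, 0.9, 66.8]
      neu_pct: [70.9, 7.1, 1.7, 97.8]
  - group_label: OA
    n: 36
    markers:
      cd45_abs: [0.5, 0.2, 0.1, 2.9]
      lym_pct: [34.8, 6.5, 4.5, 84.1]
      mon_mphi_pct: [50.5, 6.8, 12.3, 92.2]
      neu_pct: [13.6, 3.6, 1.4, 44.8]
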