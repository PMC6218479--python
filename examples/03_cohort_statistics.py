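"""Full cohort analysis on a synthetic 26-hemisphere study.

Generates a default cohort (13 patients, both hemispheres; rigidity
and bradykinesia coupled to the true beta amplitude, broadband varying
independently), fits every spectrum, and compares Spearman correlations
of the two beta biomarkers with each symptom using Hotelling's test
for dependent correlations, BH-FDR corrected.
"""

from stnbeta import analyze_cohort, gen_cohort

cohort = gen_cohort(seed=11)
res = analyze_cohort(cohort, n_boot=500, seed=0)

m = res["comparisons"].query("pathway == 'modeled'")
print(f"n = {len(res['table'])} hemispheres\n")
print(f"{'symptom':8s} {'r_without':>9s} {'r_with':>7s} {'q_without':>9s} "
      f"{'q_with':>7s} {'q_compare':>9s}")
for _, r in m.iterrows():
    print(f"{r.symptom:8s} {r.r_without:9.2f} {r.r_with:7.2f} "
          f"{r.q_without:9.3f} {r.q_with:7.3f} {r.q_compare:9.3f}")

print()
print("Isolating beta from the broadband background (r_without) recovers the")
print("planted symptom couplings; keeping the background (r_with) buries them.")
print("q_compare tests the difference of the two dependent correlations.")
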