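"""Forward-simulate a virtual patient and read off CGM metrics.

A patient at basal steady state eats a 60 g lunch, once uncovered and once
with a matched bolus; the bolus cuts the postprandial peak.  A noisy
intermittently-scanned sensor record is then sampled from the truth and
summarized with time-in-range metrics and the GMI HbA1c estimate.
"""

from glucodss import PatientPhysiology, SensorModel, observe_cgm, simulate, steady_state_basal
from glucodss.outcomes import cgm_metrics, estimate_hba1c

phys = PatientPhysiology()
basal = steady_state_basal(phys, 6.0)
print(f"basal holding fasting glucose at 6.0 mmol/L: {basal:.1f} U/day")

meal = [(12 * 60.0, 60.0, "lunch")]
uncovered = simulate(phys, basal, [], meal, horizon_days=1)
covered = simulate(phys, basal, [(12 * 60.0, 6.0)], meal, horizon_days=1)
print(f"postprandial peak: uncovered {uncovered.glucose.max():.1f} mmol/L, "
      f"with 6 U bolus {covered.glucose.max():.1f} mmol/L")

week = simulate(phys, basal, [(d * 1440 + 720.0, 6.0) for d in range(7)],
                [(d * 1440 + 720.0, 60.0, "lunch") for d in range(7)], 7)
sensor = SensorModel(noise_sd=0.4, ar_coeff=0.5)
cgm = observe_cgm(week.times, week.glucose, sensor, seed=1)
m = cgm_metrics(cgm, "overall")
print(f"one week of sensor data ({m.n_records} historic records):")
print(f"  mean glucose {m.mean_glucose:.2f} mmol/L, "
      f"time in 3.9-10: {m.pct_3_9_to_10:.1f}%, above 10: {m.pct_above_10:.1f}%")
print(f"  estimated HbA1c (GMI): {estimate_hba1c(m.mean_glucose):.2f}%")
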