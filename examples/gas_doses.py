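"""Oxygen dose arithmetic for the exposure arms of a hyperbaric study.

Builds the five exposure arms (normoxia, iso-oxic pressure control, and 100%
O2 at 1/2/3 ATA) and prints inspired PO2, alveolar PO2 and dissolved plasma
O2 for each.  The pressure-control fraction at 2 ATA comes out at exactly
10.5%: the O2 fraction that keeps the inspired dry-gas O2 pressure at the
room-air level while ambient pressure doubles.
"""

from cordquant import gas

print(f"iso-oxic fraction at 2 ATA: {gas.isooxic_fraction(2.0):.3f} (10.5% O2)")
print(f"{'arm':<24}{'FiO2':>6}{'ATA':>5}{'PIO2':>8}{'PAO2':>8}{'diss.O2':>9}")
for arm in gas.study_arms():
    print(
        f"{arm.label:<24}{arm.fio2:>6.3f}{arm.pressure_ata:>5.1f}"
        f"{arm.inspired_po2_mmhg:>8.1f}{arm.alveolar_po2_mmhg:>8.1f}"
        f"{arm.dissolved_o2_ml_dl:>9.2f}"
    )
print(
    "\nPIO2/PAO2 in mmHg, dissolved O2 in mL/dL plasma. Room air sits near\n"
    "100 mmHg alveolar PO2; 100% O2 exceeds 500 mmHg at 1 ATA and 2000 mmHg\n"
    "at 3 ATA, which is why hyperbaric O2 can supply metabolism from plasma\n"
    "alone."
)
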