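DI1: {role: DI, unit: FTE staff}
DI2: {role: DI, unit: beds}
UI1: {role: UI, unit: '% in-patient discharge rate'}
DO1: {role: DO, unit: 1000 patient-days}
DO2: {role: DO, unit: 1000 ED attendances}
DO3: {role: DO, unit: 1000 outpatient attendances}
UO1: {role: UO, unit: 'crude mortality rate (per mille)'}
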