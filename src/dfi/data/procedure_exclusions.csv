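# Inpatient ICD-9 procedure codes excluded from the treatment-frequency
# table because they are not surgical in nature, carry no anaesthetic risk,
# or are not needed for DRG assignment (coding of such procedures is
# optional, so their frequencies are unreliable). Editable.
icd9_proc_code,description
9904,Transfusion of packed cells
8952,Electrocardiogram
8744,Routine chest x-ray
9394,Respiratory medication administered by nebulizer
9925,Injection or infusion of cancer chemotherapeutic substance
9921,Injection of antibiotic
8741,CAT scan of thorax
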