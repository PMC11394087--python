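stomach_id,tl_mm,site,date
S01,303.5,,
S02,310.4,,
S03,317.4,,
S04,324.4,,
S05,331.4,,
S06,338.3,,
S07,345.3,,
S08,352.2,,
S09,359.2,,
S10,366.2,,
S11,374.6,,
S12,384.6,,
S13,394.5,,
S14,404.5,,
S15,414.5,,
S16,424.4,,
S17,434.4,,
S18,441.8,,
S19,446.8,,
S20,451.8,,
S21,456.8,,
S22,461.7,,
S23,466.7,,
S24,471.7,,
S25,476.7,,
S26,481.6,,
S27,486.6,,
S28,491.6,,
S29,496.6,,
S30,501.5,,
S31,506.5,,
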