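item_id,subscale,lambda_general,lambda_specific
SEQ2 Q3/SEQ3 Q8,Speech,0.436,0.730
SP1 Q6/SP2 Q6,Speech,0.318,0.737
SP1 Q7/SP2 Q7,Speech,0.421,0.848
SEQ2 Q19/SEQ3 Q53,Pain/Temperature,0.428,0.681
SP1 Q42/SP2 Q23/SP2 Q24,Pain/Temperature,0.469,0.854
SEQ3 Q56,Pain/Temperature,0.458,0.470
SEQ2 Q10/SEQ3 Q22/SEQ3 Q23,,0.537,
SP1 Q46/SP2 Q26,,0.473,
SEQ2 Q4/SEQ3 Q4,,0.547,
SP1 Q125,Olfactory,0.563,0.647
SEQ3 Q69,Olfactory,0.449,0.561
SEQ3 Q74,,0.444,
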