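item_id,subscale,lambda_general,lambda_specific
SEQ2 Q9/SEQ3 Q17,Visual,0.681,0.421
SP1 Q97/SP2 Q80/SP2 Q81,Visual,0.592,0.297
SEQ3 Q19,Visual,0.663,0.326
SEQ3 Q27,Visual,0.543,0.563
SEQ3 Q29,Visual,0.526,0.482
SEQ3 Q30,Visual,0.585,0.478
SP1 Q45/SP2 Q21/SP2 Q25,Tactile,0.600,0.355
SEQ2 Q36f/SEQ3 Q45,Tactile,0.549,0.698
SEQ3 Q37,Tactile,0.437,0.398
SEQ3 Q50,Tactile,0.666,0.149
SEQ2 Q25/SEQ3 Q62,Oral Tactile,0.453,0.790
SP1 Q64,Oral Tactile,0.439,0.852
SP1 Q65,Oral Tactile,0.427,0.769
SEQ3 Q71,Oral Tactile,0.527,0.706
SP1 Q24/SP1 Q25/SP2 Q27,Movement,0.613,0.480
SEQ2 Q27/SEQ3 Q76,Movement,0.624,0.355
SP1 Q84/SP2 Q60,Movement,0.602,0.157
SP1 Q26,Movement,0.684,0.652
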