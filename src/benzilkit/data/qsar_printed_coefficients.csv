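# Published (integer-rounded) QSAR coefficients per receptor:
# BE = b_ip*IP + b_ea*EA + b_s*S + b_omega*omega + intercept.
# Stored for sign/discrepancy comparison only; never used as the model of record.
receptor,b_ip,b_ea,b_s,b_omega,intercept
3WMT,-101,53,-493,6,784
2H4Z,-556,-269,-4305,146,6717
2EEP,-336,-101,-2433,76,3809
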