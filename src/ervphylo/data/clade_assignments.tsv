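clade_id	focal_group	pattern
1.2	Chiroptera	originated_from
1.7	Chiroptera	originated_from
1.11	Chiroptera	originated_from
1.9	Rodentia	originated_from
1.12	Rodentia	originated_from
1.13	Rodentia	originated_from
1.14	Rodentia	originated_from
1.16	Rodentia	originated_from
2.3	Rodentia	originated_from
2.4	Rodentia	originated_from
2.5	Rodentia	originated_from
2.6	Rodentia	originated_from
2.7	Rodentia	originated_from
2.8	Rodentia	originated_from
2.10	Rodentia	originated_from
2.12	Rodentia	originated_from
2.13	Rodentia	originated_from
1.1	Chiroptera	transmitted_via
1.3	Chiroptera	transmitted_via
1.6	Chiroptera	transmitted_via
1.15	Rodentia	transmitted_via
2.11	Rodentia	transmitted_via
2.14	Rodentia	transmitted_via
1.5	Chiroptera	received_by
1.8	Chiroptera	received_by
1.10	Chiroptera	received_by
2.1	Chiroptera	received_by
2.2	Chiroptera	received_by
2.9	Chiroptera	received_by
2.11	Chiroptera	received_by
1.4	Rodentia	received_by
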